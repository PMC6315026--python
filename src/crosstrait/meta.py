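"""Fixed-effects inverse-variance meta-analysis with heterogeneity diagnostics."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MetaResult", "ivw_meta", "meta_table", "log_or", "odds_ratio"]


@dataclass
class MetaResult:
    beta_meta: float
    se_meta: float
    z_meta: float
    p_meta: float
    q_stat: float
    q_df: int
    i2: float  # percentage in [0, 100]
    n_studies: int


def log_or(odds_ratio: float) -> float:
    return math.log(odds_ratio)


def odds_ratio(beta: float) -> float:
    return math.exp(beta)


def ivw_meta(per_study: Sequence[tuple[float, float]]) -> MetaResult:
    """Combine per-study (beta, se) pairs with inverse-variance weights.

    Cochran's Q tests heterogeneity; I2 = max(0, (Q - df) / Q) * 100
    quantifies the proportion of total variation due to it.
    """
    if len(per_study) == 0:
        raise ValueError("need at least one study")
    betas = np.array([b for b, _ in per_study], dtype=float)
    ses = np.array([s for _, s in per_study], dtype=float)
    for i, s in enumerate(ses):
        if s <= 0:
            raise ValueError(f"study {i}: SE must be > 0 (got {s})")
    w = 1.0 / ses**2
    beta_meta = float(np.sum(w * betas) / np.sum(w))
    se_meta = float(1.0 / math.sqrt(np.sum(w)))
    z = beta_meta / se_meta
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = float(np.sum(w * (betas - beta_meta) ** 2))
    df = len(per_study) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return MetaResult(beta_meta=beta_meta, se_meta=se_meta, z_meta=float(z),
                      p_meta=p, q_stat=q, q_df=df, i2=i2, n_studies=len(per_study))


def meta_table(stacked: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP meta-analysis of a stacked study table.

    ``stacked`` needs columns SNP, STUDY, BETA, SE (log-odds scale); one
    output row per SNP with the combined effect plus Q and I2 columns.
    """
    for col in ("SNP", "STUDY", "BETA", "SE"):
        if col not in stacked.columns:
            raise ValueError(f"stacked table lacks column {col}")
    rows = []
    for snp, group in stacked.groupby("SNP", sort=True):
        res = ivw_meta(list(zip(group["BETA"], group["SE"])))
        rows.append((snp, res.beta_meta, res.se_meta, res.z_meta, res.p_meta,
                     res.q_stat, res.q_df, res.i2, res.n_studies))
    return pd.DataFrame(rows, columns=["SNP", "BETA", "SE", "Z", "P",
                                       "Q", "Q_DF", "I2", "N_STUDIES"])
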