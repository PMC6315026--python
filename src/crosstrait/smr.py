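"""Summary-data Mendelian randomization with heterogeneity testing.

Links eQTL and GWAS summary statistics: if ``b_zx`` is the effect of
variant z on expression x and ``b_zy`` its effect on the trait y, then
``b_xy = b_zy / b_zx`` estimates the effect of expression on the trait.
A single shared causal variant (pleiotropy) makes ``b_xy`` identical
across SNPs in LD with it; heterogeneity across instruments therefore
indicates linkage of distinct causal variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EqtlRecord",
    "SmrResult",
    "HeidiResult",
    "smr_test",
    "heidi_test",
    "run_smr_scan",
]

#: Relaxed instrument threshold for HEIDI SNP selection (chi2(1) > 10).
HEIDI_INSTRUMENT_P = 1.57e-3
HEIDI_R2_RANGE = (0.05, 0.90)
HEIDI_MAX_SNPS = 20
HEIDI_MIN_SNPS = 3


@dataclass
class EqtlRecord:
    """Marginal eQTL association of one variant with one expression probe."""

    probe: str
    gene: str
    snp_id: str
    b_zx: float
    se_zx: float
    p_zx: float

    def __post_init__(self) -> None:
        if self.se_zx <= 0:
            raise ValueError(f"{self.snp_id}: se_zx must be > 0")

    @property
    def z_zx(self) -> float:
        return self.b_zx / self.se_zx


@dataclass
class HeidiResult:
    p: float | None
    n_used: int
    reason: str | None = None


@dataclass
class SmrResult:
    probe: str
    top_snp: str
    b_xy: float
    se_xy: float
    t_smr: float
    p_smr: float
    p_heidi: float | None = None
    n_heidi_snps: int = 0
    heidi_reason: str | None = None
    passes_smr: bool | None = None
    heterogeneous: bool | None = None


def smr_test(eqtl: EqtlRecord, gwas) -> SmrResult:
    """Test for a shared signal between an eQTL instrument and the GWAS.

    ``gwas`` is any object with ``beta`` and ``se`` attributes for the same
    variant on the same effect allele (alignment is the caller's job).
    The statistic is ``t = z_zx^2 z_zy^2 / (z_zx^2 + z_zy^2)`` with a
    chi-square(1) p-value.
    """
    snp = getattr(gwas, "variant", gwas)
    gwas_snp = getattr(snp, "snp_id", None)
    if gwas_snp is not None and gwas_snp != eqtl.snp_id:
        raise ValueError(f"SNP mismatch: eQTL {eqtl.snp_id}, GWAS {gwas_snp}")
    if eqtl.b_zx == 0:
        raise ValueError(f"{eqtl.snp_id}: b_zx is zero; b_xy undefined")
    b_zy, se_zy = float(gwas.beta), float(gwas.se)
    if se_zy <= 0:
        raise ValueError("GWAS SE must be > 0")
    z_zx = eqtl.z_zx
    z_zy = b_zy / se_zy
    b_xy = b_zy / eqtl.b_zx
    denom = z_zx**2 + z_zy**2
    t_smr = (z_zx**2 * z_zy**2) / denom if denom > 0 else 0.0
    p_smr = float(stats.chi2.sf(t_smr, df=1)) if t_smr > 0 else 1.0
    se_xy = abs(b_xy) / math.sqrt(t_smr) if t_smr > 0 else math.inf
    return SmrResult(probe=eqtl.probe, top_snp=eqtl.snp_id, b_xy=b_xy,
                     se_xy=se_xy, t_smr=t_smr, p_smr=p_smr)


def _heidi_covariance(b_zx, se_zx, b_zy, se_zy, r, idx, top):
    """Delta-method covariance of d_i = b_xy(i) - b_xy(top).

    eQTL and GWAS samples are independent; within each, LD induces
    cov(b_i, b_j) = r_ij * se_i * se_j.
    """
    k = len(idx)
    V = np.empty((k, k))
    bx, sx = b_zx[idx], se_zx[idx]
    by, sy = b_zy[idx], se_zy[idx]
    bxt, sxt = b_zx[top], se_zx[top]
    byt, syt = b_zy[top], se_zy[top]
    r_it = r[idx, top]
    for a in range(k):
        for b in range(a, k):
            r_ij = r[idx[a], idx[b]]
            cov = (r_ij * sy[a] * sy[b] / (bx[a] * bx[b])
                   + (by[a] * by[b] / (bx[a]**2 * bx[b]**2)) * r_ij * sx[a] * sx[b]
                   + syt**2 / bxt**2
                   + (byt**2 / bxt**4) * sxt**2
                   - r_it[a] * sy[a] * syt / (bx[a] * bxt)
                   - r_it[b] * sy[b] * syt / (bx[b] * bxt)
                   - (by[a] * byt / (bx[a]**2 * bxt**2)) * r_it[a] * sx[a] * sxt
                   - (by[b] * byt / (bx[b]**2 * bxt**2)) * r_it[b] * sx[b] * sxt)
            V[a, b] = V[b, a] = cov
    return V


def heidi_test(
    cis_eqtl: Sequence[EqtlRecord],
    cis_gwas: Sequence,
    ld: np.ndarray,
    top_snp: str,
    p_instrument: float = HEIDI_INSTRUMENT_P,
    r2_range: tuple[float, float] = HEIDI_R2_RANGE,
    max_snps: int = HEIDI_MAX_SNPS,
    n_draws: int = 50_000,
    seed: int = 0,
) -> HeidiResult:
    """Heterogeneity test across instruments in a cis region.

    Selects SNPs with instrument p below ``p_instrument`` and r2 with the
    top SNP within ``r2_range``, caps at the ``max_snps`` strongest, forms
    per-SNP deviations from the top SNP's ``b_xy`` and evaluates the sum of
    squared standardized deviations against its null distribution by
    seeded Monte-Carlo from the delta-method multivariate normal.
    """
    ld = np.asarray(ld, dtype=float)
    snps = [e.snp_id for e in cis_eqtl]
    if len(set(snps)) != len(snps):
        raise ValueError("duplicate SNPs in cis region")
    if top_snp not in snps:
        raise ValueError(f"top SNP {top_snp} not in cis region")
    if ld.shape != (len(snps), len(snps)):
        raise ValueError("LD matrix shape does not match cis SNP count")
    gwas_by_pos = list(cis_gwas)
    if len(gwas_by_pos) != len(snps):
        raise ValueError("GWAS records must match cis eQTL records one-to-one")

    top = snps.index(top_snp)
    b_zx = np.array([e.b_zx for e in cis_eqtl])
    se_zx = np.array([e.se_zx for e in cis_eqtl])
    p_zx = np.array([e.p_zx for e in cis_eqtl])
    b_zy = np.array([float(g.beta) for g in gwas_by_pos])
    se_zy = np.array([float(g.se) for g in gwas_by_pos])

    r2 = ld[:, top] ** 2
    eligible = np.flatnonzero(
        (p_zx < p_instrument)
        & (r2 >= r2_range[0]) & (r2 <= r2_range[1])
        & (np.arange(len(snps)) != top)
        & (b_zx != 0)
    )
    # canonical order (strongest instrument first, id tiebreak) so the
    # Monte-Carlo p does not depend on the input ordering of cis SNPs
    order = np.lexsort((np.array(snps, dtype=object)[eligible], p_zx[eligible]))
    eligible = eligible[order][:max_snps]
    if eligible.size < HEIDI_MIN_SNPS:
        return HeidiResult(p=None, n_used=int(eligible.size),
                           reason=f"only {eligible.size} eligible SNPs (need >= {HEIDI_MIN_SNPS})")

    b_xy = b_zy / b_zx
    d = b_xy[eligible] - b_xy[top]
    V = _heidi_covariance(b_zx, se_zx, b_zy, se_zy, ld, eligible, top)
    sd = np.sqrt(np.diag(V))
    t_obs = float(np.sum((d / sd) ** 2))

    rng = np.random.default_rng(seed)
    jitter = 0.0
    for _ in range(6):
        try:
            L = np.linalg.cholesky(V + jitter * np.eye(len(d)))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-12 * np.trace(V) / len(d))
    else:
        raise np.linalg.LinAlgError("HEIDI covariance not positive definite")
    draws = rng.standard_normal((n_draws, len(d))) @ L.T
    t_null = np.sum((draws / sd) ** 2, axis=1)
    p = float((1 + np.count_nonzero(t_null >= t_obs)) / (1 + n_draws))
    return HeidiResult(p=p, n_used=int(eligible.size))


def run_smr_scan(
    eqtl_catalog: pd.DataFrame,
    gwas: pd.DataFrame,
    n_probes_tested: int,
    alpha: float = 0.05,
    instrument_p: float = 5e-8,
    heidi_alpha: float = 0.05,
    ld_matrix: np.ndarray | None = None,
    ld_snps: Sequence[str] | None = None,
    n_draws: int = 50_000,
    seed: int = 0,
) -> tuple[list[SmrResult], dict]:
    """Scan probes: top-instrument SMR, Bonferroni gate, then HEIDI.

    ``eqtl_catalog`` needs columns probe, gene, SNP, B_ZX, SE_ZX, P_ZX;
    ``gwas`` is a canonical summary-statistics frame.  Probes whose SMR p
    falls below ``alpha / n_probes_tested`` advance to HEIDI when an LD
    matrix over ``ld_snps`` is supplied.
    """
    if n_probes_tested < 1:
        raise ValueError("n_probes_tested must be >= 1")
    threshold = alpha / n_probes_tested
    gwas_idx = gwas.set_index("SNP")
    results: list[SmrResult] = []
    skipped_probes = 0
    for probe, group in eqtl_catalog.groupby("probe", sort=True):
        group = group[group["SNP"].isin(gwas_idx.index)]
        instruments = group[group["P_ZX"] < instrument_p]
        if instruments.empty:
            skipped_probes += 1
            continue
        top_row = instruments.loc[instruments["P_ZX"].idxmin()]
        top = EqtlRecord(probe=str(probe), gene=str(top_row.get("gene", "")),
                         snp_id=top_row["SNP"], b_zx=top_row["B_ZX"],
                         se_zx=top_row["SE_ZX"], p_zx=top_row["P_ZX"])
        grow = gwas_idx.loc[top.snp_id]
        result = smr_test(top, _GwasView(grow["BETA"], grow["SE"]))
        result.passes_smr = result.p_smr < threshold
        if result.passes_smr and ld_matrix is not None and ld_snps is not None:
            order = {s: i for i, s in enumerate(ld_snps)}
            rows = group[group["SNP"].isin(order)]
            cis = [EqtlRecord(str(probe), str(r.get("gene", "")), r["SNP"],
                              r["B_ZX"], r["SE_ZX"], r["P_ZX"])
                   for _, r in rows.iterrows()]
            gv = [_GwasView(gwas_idx.at[r.snp_id, "BETA"], gwas_idx.at[r.snp_id, "SE"])
                  for r in cis]
            keep = [order[r.snp_id] for r in cis]
            sub_ld = np.asarray(ld_matrix)[np.ix_(keep, keep)]
            heidi = heidi_test(cis, gv, sub_ld, top.snp_id,
                               n_draws=n_draws, seed=seed)
            result.p_heidi = heidi.p
            result.n_heidi_snps = heidi.n_used
            result.heidi_reason = heidi.reason
            if heidi.p is not None:
                result.heterogeneous = heidi.p < heidi_alpha
        results.append(result)
    report = {
        "n_probes": int(eqtl_catalog["probe"].nunique()),
        "n_tested": len(results),
        "n_skipped_no_instrument": skipped_probes,
        "smr_threshold": threshold,
        "n_passing_smr": sum(bool(r.passes_smr) for r in results),
    }
    return results, report


class _GwasView:
    """Minimal beta/se holder for smr_test."""

    __slots__ = ("beta", "se")

    def __init__(self, beta: float, se: float):
        self.beta = float(beta)
        self.se = float(se)
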