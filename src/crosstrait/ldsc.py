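"""LD scores and univariate / cross-trait / stratified LD-score regression.

The chi-square statistic of a SNP absorbs the signal of every SNP it tags,
so regressing per-SNP chi-square on the LD score l_j = sum_k r2(j, k)
estimates heritability from its slope, and regressing the cross-trait
product z1_j * z2_j on l_j estimates genetic covariance, with the free
intercept absorbing confounding and sample overlap.  Uncertainty comes
from a delete-one-block jackknife over contiguous genomic blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LDScoreEntry",
    "LdscFit",
    "PartitionedFit",
    "compute_ld_scores",
    "entries_from_frame",
    "write_ld_scores",
    "read_ld_scores",
    "fit_univariate",
    "fit_cross_trait",
    "fit_partitioned",
    "block_jackknife",
]

DEFAULT_N_BLOCKS = 200


@dataclass
class LDScoreEntry:
    snp_id: str
    ell_total: float
    ell_by_category: dict[str, float] = field(default_factory=dict)


@dataclass
class LdscFit:
    """Result of one LD-score regression (univariate or cross-trait)."""

    slope: float
    intercept: float
    n_blocks: int
    n_snps: int
    kind: str = "h2"
    h2_obs: float | None = None
    se_h2: float | None = None
    rho_g: float | None = None
    se_rho_g: float | None = None
    rg: float | None = None
    se_rg: float | None = None
    p_rg: float | None = None
    se_slope: float | None = None
    se_intercept: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items() if v is not None}


@dataclass
class PartitionedFit:
    categories: list[str]
    prop_snps: dict[str, float]
    prop_h2: dict[str, float]
    enrichment: dict[str, float]
    se_enrichment: dict[str, float]
    intercept: float
    n_snps: int
    n_blocks: int
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "category": self.categories,
            "prop_snps": [self.prop_snps[c] for c in self.categories],
            "prop_h2": [self.prop_h2[c] for c in self.categories],
            "enrichment": [self.enrichment[c] for c in self.categories],
            "se_enrichment": [self.se_enrichment[c] for c in self.categories],
        })


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    return Xc / sd


def compute_ld_scores(
    panel,
    window: int | None = None,
    window_bp: int | None = None,
    categories: Mapping[str, Sequence[str]] | None = None,
    adjusted: bool = False,
    chunk: int = 512,
) -> pd.DataFrame:
    """Windowed LD scores l_j = sum over neighbours k of r2(j, k), self included.

    ``window`` is a SNP-count radius (default: whole panel); ``window_bp``
    restricts by base-pair distance instead.  ``adjusted`` applies the
    finite-sample correction r2 - (1 - r2) / (n - 2).  ``categories`` maps
    names to SNP-id sets and yields per-category partial scores L2_<name>.
    """
    m = panel.m
    n = panel.n_individuals
    if window is not None and window < 1:
        raise ValueError("window must cover at least 1 SNP")
    w = m if window is None else int(window)
    X = _standardize_columns(np.asarray(panel.genotypes, dtype=float))
    positions = panel.positions
    snp_ids = panel.snp_ids

    cat_names = list(categories) if categories else []
    cat_masks = {}
    for name in cat_names:
        members = set(categories[name])
        cat_masks[name] = np.array([s in members for s in snp_ids])

    ell = np.zeros(m)
    ell_cat = {name: np.zeros(m) for name in cat_names}
    for a in range(0, m, chunk):
        b = min(a + chunk, m)
        lo, hi = max(0, a - w), min(m, b + w)
        C = (X[:, lo:hi].T @ X[:, a:b]) / n
        r2 = C * C
        if adjusted:
            r2 = r2 - (1.0 - r2) / (n - 2)
        rows = np.arange(lo, hi)[:, None]
        cols = np.arange(a, b)[None, :]
        mask = np.abs(rows - cols) <= w
        if window_bp is not None:
            mask &= np.abs(positions[lo:hi, None] - positions[None, a:b]) <= window_bp
        r2 = np.where(mask, r2, 0.0)
        ell[a:b] = r2.sum(axis=0)
        for name in cat_names:
            ell_cat[name][a:b] = r2[cat_masks[name][lo:hi]].sum(axis=0)

    out = pd.DataFrame({
        "SNP": snp_ids,
        "CHR": [v.chrom for v in panel.variants],
        "BP": positions,
        "L2": ell,
    })
    for name in cat_names:
        out[f"L2_{name}"] = ell_cat[name]
    return out


def entries_from_frame(df: pd.DataFrame) -> list[LDScoreEntry]:
    cat_cols = [c for c in df.columns if c.startswith("L2_")]
    return [
        LDScoreEntry(
            snp_id=row["SNP"], ell_total=float(row["L2"]),
            ell_by_category={c[3:]: float(row[c]) for c in cat_cols})
        for _, row in df.iterrows()
    ]


def write_ld_scores(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_ld_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# weighted regression with delete-one-block jackknife via per-block sums
# ---------------------------------------------------------------------------

def _block_slices(n: int, n_blocks: int) -> list[np.ndarray]:
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    if n < n_blocks:
        raise ValueError(f"fewer SNPs ({n}) than jackknife blocks ({n_blocks})")
    return np.array_split(np.arange(n), n_blocks)


def _wls_block_sums(x, y, w, blocks):
    """Per-block sufficient statistics for WLS of y on [x, 1]."""
    stats_per_block = np.empty((len(blocks), 5))
    for i, idx in enumerate(blocks):
        wi, xi, yi = w[idx], x[idx], y[idx]
        stats_per_block[i] = (wi.sum(), (wi * xi).sum(), (wi * xi * xi).sum(),
                              (wi * yi).sum(), (wi * xi * yi).sum())
    return stats_per_block


def _solve_wls(s):
    sw, swx, swxx, swy, swxy = s
    denom = sw * swxx - swx * swx
    slope = (sw * swxy - swx * swy) / denom
    intercept = (swy - slope * swx) / sw
    return slope, intercept


def _ols_line(x, y):
    slope, intercept = np.polyfit(x, y, 1)
    return slope, intercept


def _univariate_weights(ell, chi2):
    """Two-pass weights: 1 / (max(l, 1) * fitted_expectation^2)."""
    b, a = _ols_line(ell, chi2)
    fitted = np.clip(a + b * ell, 0.1, None)
    return 1.0 / (np.maximum(ell, 1.0) * fitted**2)


def _prepare(ss: pd.DataFrame, scores: pd.DataFrame):
    score_cols = [c for c in scores.columns if c == "SNP" or c.startswith("L2")]
    merged = ss.merge(scores[score_cols], on="SNP", how="inner")
    merged = merged.sort_values(["CHR", "BP", "SNP"], kind="mergesort").reset_index(drop=True)
    return merged


def _chi2_cap_mask(chi2: np.ndarray, n_eff: float, chi2_max: float | None = None) -> np.ndarray:
    cap = max(80.0, 0.001 * n_eff) if chi2_max is None else chi2_max
    keep = np.isfinite(chi2) & (chi2 <= cap)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"{dropped} SNPs dropped (non-finite or chi2 > {cap:g})")
    return keep


def fit_univariate(
    ss: pd.DataFrame,
    scores: pd.DataFrame,
    m_snps: int,
    n_blocks: int = DEFAULT_N_BLOCKS,
    weights: np.ndarray | None = None,
    chi2_max: float | None = None,
) -> LdscFit:
    """Heritability from weighted regression of chi-square on the LD score.

    ``m_snps`` is the total SNP count over which heritability is defined
    (at least the regression SNP count); h2 = slope * M / N on the
    observed scale, with jackknife standard errors over ``n_blocks``
    contiguous blocks.
    """
    merged = _prepare(ss, scores)
    chi2 = (merged["Z"].to_numpy() ** 2)
    n_per_snp = (merged["N_CAS"] + merged["N_CON"]).to_numpy(dtype=float)
    n_eff = float(n_per_snp.mean())
    keep = _chi2_cap_mask(chi2, n_eff, chi2_max)
    merged, chi2, n_per_snp = merged[keep], chi2[keep], n_per_snp[keep]
    if len(merged) < 2:
        raise ValueError("too few SNPs for regression")
    if m_snps < len(merged):
        raise ValueError("m_snps must be >= the number of regression SNPs")
    ell = merged["L2"].to_numpy(dtype=float)
    w = _univariate_weights(ell, chi2) if weights is None else np.asarray(weights)[keep]
    blocks = _block_slices(len(merged), n_blocks)
    sums = _wls_block_sums(ell, chi2, w, blocks)
    total = sums.sum(axis=0)
    slope, intercept = _solve_wls(total)
    n_eff = float(n_per_snp.mean())
    h2 = slope * m_snps / n_eff

    loo = total[None, :] - sums
    loo_params = np.array([_solve_wls(s) for s in loo])
    B = len(blocks)
    fac = (B - 1) / B

    def jse(values):
        return float(np.sqrt(fac * np.sum((values - values.mean()) ** 2)))

    return LdscFit(
        slope=float(slope), intercept=float(intercept), kind="h2",
        h2_obs=float(h2), se_h2=jse(loo_params[:, 0] * m_snps / n_eff),
        se_slope=jse(loo_params[:, 0]), se_intercept=jse(loo_params[:, 1]),
        n_blocks=B, n_snps=len(merged))


def _align_pair(ss1: pd.DataFrame, ss2: pd.DataFrame) -> pd.DataFrame:
    """Merge two harmonized studies on SNP, re-checking allele concordance."""
    merged = ss1.merge(ss2, on="SNP", suffixes=("_1", "_2"))
    same = (merged["A1_1"] == merged["A1_2"]) & (merged["A2_1"] == merged["A2_2"])
    swapped = (merged["A1_1"] == merged["A2_2"]) & (merged["A2_1"] == merged["A1_2"])
    bad = ~(same | swapped)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} SNPs dropped: irreconcilable alleles across traits")
        merged = merged[~bad].copy()
        same, swapped = same[~bad], swapped[~bad]
    merged.loc[swapped, "Z_2"] = -merged.loc[swapped, "Z_2"]
    return merged


def fit_cross_trait(
    ss1: pd.DataFrame,
    ss2: pd.DataFrame,
    scores: pd.DataFrame,
    m_snps: int,
    h2_fits: tuple[LdscFit, LdscFit] | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
    chi2_max: float | None = None,
) -> LdscFit:
    """Genetic covariance and correlation from the z1*z2 regression.

    rho_g = slope * M / sqrt(N1 N2); rg = rho_g / sqrt(h2_1 h2_2).  The
    jackknife re-estimates both heritabilities and the covariance in every
    leave-one-block-out sample, so the rg standard error reflects the full
    ratio.  The intercept absorbs sample overlap.  A non-positive
    heritability leaves rg undefined with an explanatory flag.
    """
    merged = _align_pair(ss1, ss2)
    merged = merged.rename(columns={"CHR_1": "CHR", "BP_1": "BP"})
    merged = _prepare(merged, scores)
    z1 = merged["Z_1"].to_numpy(dtype=float)
    z2 = merged["Z_2"].to_numpy(dtype=float)
    n1 = float((merged["N_CAS_1"] + merged["N_CON_1"]).mean())
    n2 = float((merged["N_CAS_2"] + merged["N_CON_2"]).mean())
    keep = _chi2_cap_mask(z1**2, n1, chi2_max) & _chi2_cap_mask(z2**2, n2, chi2_max)
    merged, z1, z2 = merged[keep], z1[keep], z2[keep]
    if m_snps < len(merged):
        raise ValueError("m_snps must be >= the number of regression SNPs")
    ell = merged["L2"].to_numpy(dtype=float)
    y = z1 * z2

    # provisional expectations for the variance-motivated weights
    b1, a1 = _ols_line(ell, z1**2)
    b2, a2 = _ols_line(ell, z2**2)
    bc, ac = _ols_line(ell, y)
    f1 = np.clip(a1 + b1 * ell, 0.1, None)
    f2 = np.clip(a2 + b2 * ell, 0.1, None)
    g = ac + bc * ell
    w_cross = 1.0 / (np.maximum(ell, 1.0) * (f1 * f2 + g**2))
    w1 = 1.0 / (np.maximum(ell, 1.0) * f1**2)
    w2 = 1.0 / (np.maximum(ell, 1.0) * f2**2)

    blocks = _block_slices(len(merged), n_blocks)
    sums_c = _wls_block_sums(ell, y, w_cross, blocks)
    sums_1 = _wls_block_sums(ell, z1**2, w1, blocks)
    sums_2 = _wls_block_sums(ell, z2**2, w2, blocks)
    tot_c, tot_1, tot_2 = (s.sum(axis=0) for s in (sums_c, sums_1, sums_2))

    slope_c, intercept_c = _solve_wls(tot_c)
    rho_g = slope_c * m_snps / np.sqrt(n1 * n2)
    if h2_fits is not None:
        h2_1, h2_2 = h2_fits[0].h2_obs, h2_fits[1].h2_obs
    else:
        h2_1 = _solve_wls(tot_1)[0] * m_snps / n1
        h2_2 = _solve_wls(tot_2)[0] * m_snps / n2

    fit = LdscFit(slope=float(slope_c), intercept=float(intercept_c), kind="rg",
                  rho_g=float(rho_g), n_blocks=len(blocks), n_snps=len(merged))
    B = len(blocks)
    fac = (B - 1) / B
    loo_rho = np.array([_solve_wls(tot_c - s)[0] for s in sums_c]) * m_snps / np.sqrt(n1 * n2)
    loo_int = np.array([_solve_wls(tot_c - s)[1] for s in sums_c])
    fit.se_rho_g = float(np.sqrt(fac * np.sum((loo_rho - loo_rho.mean()) ** 2)))
    fit.se_intercept = float(np.sqrt(fac * np.sum((loo_int - loo_int.mean()) ** 2)))
    fit.se_slope = fit.se_rho_g * np.sqrt(n1 * n2) / m_snps

    if h2_1 is None or h2_2 is None or h2_1 <= 0 or h2_2 <= 0:
        fit.flags.append("rg_undefined_nonpositive_h2")
        return fit

    fit.rg = float(rho_g / np.sqrt(h2_1 * h2_2))
    loo_h1 = np.array([_solve_wls(tot_1 - s)[0] for s in sums_1]) * m_snps / n1
    loo_h2 = np.array([_solve_wls(tot_2 - s)[0] for s in sums_2]) * m_snps / n2
    bad = (loo_h1 <= 0) | (loo_h2 <= 0)
    if bad.any():
        fit.flags.append(f"{int(bad.sum())} leave-out blocks had non-positive h2; clipped")
        loo_h1 = np.clip(loo_h1, 1e-12, None)
        loo_h2 = np.clip(loo_h2, 1e-12, None)
    loo_rg = loo_rho / np.sqrt(loo_h1 * loo_h2)
    fit.se_rg = float(np.sqrt(fac * np.sum((loo_rg - loo_rg.mean()) ** 2)))
    if fit.se_rg > 0:
        fit.p_rg = float(2.0 * stats.norm.sf(abs(fit.rg) / fit.se_rg))
    return fit


def fit_partitioned(
    ss: pd.DataFrame,
    scores: pd.DataFrame,
    m_snps: int,
    categories: Mapping[str, Sequence[str]],
    n_blocks: int = DEFAULT_N_BLOCKS,
    report_exclude: Sequence[str] = (),
    chi2_max: float | None = None,
) -> PartitionedFit:
    """Stratified regression of chi-square on per-category LD scores.

    Per-category heritability shares come from the category coefficients;
    enrichment is (share of h2) / (share of SNPs).  Overlapping categories
    are allowed.  Categories named in ``report_exclude`` (e.g. flanking
    windows) are fitted but omitted from the report.
    """
    cat_names = list(categories)
    for name in cat_names:
        if len(categories[name]) == 0:
            raise ValueError(f"category {name!r} has zero SNPs")
        if f"L2_{name}" not in scores.columns:
            raise ValueError(f"scores frame lacks column L2_{name}")
    merged = _prepare(ss, scores)
    chi2 = merged["Z"].to_numpy() ** 2
    n_eff = float((merged["N_CAS"] + merged["N_CON"]).mean())
    keep = _chi2_cap_mask(chi2, n_eff, chi2_max)
    merged, chi2 = merged[keep], chi2[keep]
    ell_tot = merged["L2"].to_numpy(dtype=float)
    X = np.column_stack([merged[f"L2_{name}"].to_numpy(dtype=float) for name in cat_names]
                        + [np.ones(len(merged))])
    w = _univariate_weights(ell_tot, chi2)
    blocks = _block_slices(len(merged), n_blocks)

    k = X.shape[1]
    xtwx_b = np.empty((len(blocks), k, k))
    xtwy_b = np.empty((len(blocks), k))
    for i, idx in enumerate(blocks):
        Xw = X[idx] * w[idx, None]
        xtwx_b[i] = Xw.T @ X[idx]
        xtwy_b[i] = Xw.T @ chi2[idx]
    xtwx, xtwy = xtwx_b.sum(axis=0), xtwy_b.sum(axis=0)

    def solve(a, b):
        cond = np.linalg.cond(a)
        if cond > 1e10:
            warnings.warn(f"collinear category scores (cond={cond:.2g}); ridge fallback")
            a = a + 1e-6 * np.trace(a) / k * np.eye(k)
        return np.linalg.solve(a, b)

    coefs = solve(xtwx, xtwy)
    counts = {name: len(set(categories[name])) for name in cat_names}
    membership = {name: set(categories[name]) for name in cat_names}

    def h2_shares(theta):
        tau = theta[:-1] / n_eff  # per-SNP h2 contribution of each category
        per_cat = {}
        for name in cat_names:
            total_c = 0.0
            for other in cat_names:
                overlap = len(membership[name] & membership[other])
                total_c += tau[cat_names.index(other)] * overlap
            per_cat[name] = total_c
        total = sum(tau[i] * counts[cat_names[i]] for i in range(len(cat_names)))
        return per_cat, total

    per_cat, total_h2 = h2_shares(coefs)
    prop_snps = {name: counts[name] / m_snps for name in cat_names}
    prop_h2 = {name: (per_cat[name] / total_h2 if total_h2 != 0 else np.nan)
               for name in cat_names}
    enrichment = {name: prop_h2[name] / prop_snps[name] for name in cat_names}

    B = len(blocks)
    fac = (B - 1) / B
    loo_enrich = {name: np.empty(B) for name in cat_names}
    for i in range(B):
        theta_i = solve(xtwx - xtwx_b[i], xtwy - xtwy_b[i])
        pc, tot = h2_shares(theta_i)
        for name in cat_names:
            loo_enrich[name][i] = (pc[name] / tot) / prop_snps[name] if tot != 0 else np.nan
    se = {}
    for name in cat_names:
        vals = loo_enrich[name]
        se[name] = float(np.sqrt(fac * np.nansum((vals - np.nanmean(vals)) ** 2)))

    reported = [c for c in cat_names if c not in set(report_exclude)]
    return PartitionedFit(
        categories=reported,
        prop_snps={c: prop_snps[c] for c in reported},
        prop_h2={c: prop_h2[c] for c in reported},
        enrichment={c: enrichment[c] for c in reported},
        se_enrichment={c: se[c] for c in reported},
        intercept=float(coefs[-1]), n_snps=len(merged), n_blocks=B)


def block_jackknife(
    statistic: Callable[[np.ndarray], float],
    items: Sequence,
    n_blocks: int,
) -> tuple[float, float]:
    """Delete-one-block jackknife of an arbitrary statistic.

    ``statistic`` receives an index array into ``items`` (ordered by genome
    position by the caller).  Returns the full-sample estimate and
    SE = sqrt((B-1)/B * sum((theta_b - mean)^2)).
    """
    n = len(items)
    blocks = _block_slices(n, n_blocks)
    full_idx = np.arange(n)
    estimate = float(statistic(full_idx))
    loo = np.empty(len(blocks))
    for i, idx in enumerate(blocks):
        mask = np.ones(n, dtype=bool)
        mask[idx] = False
        val = statistic(full_idx[mask])
        if not np.isfinite(val):
            raise ValueError(f"statistic non-finite when leaving out block {i}")
        loo[i] = val
    B = len(blocks)
    se = float(np.sqrt((B - 1) / B * np.sum((loo - loo.mean()) ** 2)))
    return estimate, se
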