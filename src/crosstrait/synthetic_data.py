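"""Generators for every input the pipeline consumes.

Produces block-LD reference panels, bivariate case-control summary
statistics with known heritability and genetic correlation, cis-eQTL loci
under pleiotropy/linkage/null scenarios, peak interval sets with plantable
enrichment, and the packaged risk-locus table fixture.  All generators are
bit-reproducible under a fixed seed.

Summary statistics are simulated directly at the Z-score level from
block-wise multivariate normals: within each LD block, marginal Z-scores
have mean sqrt(N) * R @ beta_causal and noise covariance R, where R is the
block's empirical dosage correlation matrix.  This matches exactly the
moment structure the LD-score regression estimator assumes, so generator
and estimator can be cross-checked against the same identity
E[chi2_j] = 1 + N h2 l_j / M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .smr import EqtlRecord
from .sumstats_io import CANONICAL_COLUMNS, VariantRecord

__all__ = [
    "SimulationConfig",
    "LDPanel",
    "Table1Row",
    "Table1Fixture",
    "make_ld_panel",
    "simulate_bivariate_sumstats",
    "simulate_eqtl_locus",
    "EqtlLocusSim",
    "make_peak_fixture",
    "table1_fixture",
    "reference_from_panel",
]

_NONAMBIGUOUS_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                       ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Generative parameters for a bivariate GWAS experiment."""

    m_snps: int = 5000
    n1_cases: int = 10_000
    n1_controls: int = 10_000
    n2_cases: int = 5_000
    n2_controls: int = 5_000
    h2_1: float = 0.1
    h2_2: float = 0.25
    rg: float = 0.4
    n_overlap: int = 0
    ld_block_size: int = 50
    ld_decay: float = 0.9
    n_ref: int = 500
    ambiguous_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_1 <= 1.0 or not 0.0 <= self.h2_2 <= 1.0:
            raise ValueError("heritabilities must lie in [0, 1]")
        if not -1.0 <= self.rg <= 1.0:
            raise ValueError("rg must lie in [-1, 1]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must lie in [0, 1)")
        if self.n_overlap < 0:
            raise ValueError("n_overlap must be >= 0")

    @property
    def n1(self) -> int:
        return self.n1_cases + self.n1_controls

    @property
    def n2(self) -> int:
        return self.n2_cases + self.n2_controls


@dataclass
class LDPanel:
    """Reference panel: variant metadata plus an individuals x SNPs dosage matrix.

    Dosages are Gaussian with per-SNP mean 2*MAF and variance 2*MAF*(1-MAF),
    correlated within blocks and independent across block boundaries by
    construction (an idealisation of imputed dosages; see ``hard_calls``
    for a rounded 0/1/2 view).
    """

    variants: list[VariantRecord]
    genotypes: np.ndarray
    block_bounds: list[tuple[int, int]]
    _chol_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.genotypes.shape[1] != len(self.variants):
            raise ValueError("genotype column count must equal variant count")

    @property
    def m(self) -> int:
        return len(self.variants)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.variants]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants])

    def block_of(self, index: int) -> int:
        for b, (s, e) in enumerate(self.block_bounds):
            if s <= index < e:
                return b
        raise IndexError(index)

    def block_corr(self, block: int) -> np.ndarray:
        s, e = self.block_bounds[block]
        if e - s == 1:
            return np.ones((1, 1))
        return np.corrcoef(self.genotypes[:, s:e], rowvar=False)

    def block_chol(self, block: int, max_jitter: float = 1e-4) -> np.ndarray:
        """Cholesky factor of the block correlation, ridge-jittered if needed."""
        if block in self._chol_cache:
            return self._chol_cache[block]
        R = self.block_corr(block)
        jitter = 0.0
        while True:
            try:
                L = np.linalg.cholesky(R + jitter * np.eye(len(R)))
                break
            except np.linalg.LinAlgError:
                jitter = max(jitter * 10, 1e-10)
                if jitter > max_jitter:
                    raise
        if jitter:
            warnings.warn(f"block {block}: correlation ridge-regularized with jitter {jitter:g}")
        self._chol_cache[block] = L
        return L

    def hard_calls(self) -> np.ndarray:
        """Rounded, clipped 0/1/2 genotypes."""
        return np.clip(np.rint(self.genotypes), 0, 2).astype(np.int8)

    def variants_frame(self) -> pd.DataFrame:
        rows = [(v.snp_id, v.chrom, v.pos, v.a1, v.a2, v.maf) for v in self.variants]
        return pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "A1", "A2", "MAF"])


def make_ld_panel(config: SimulationConfig, rng: np.random.Generator | None = None) -> LDPanel:
    """Build a reference panel with AR(1)-decaying within-block correlation.

    MAFs are uniform on [0.05, 0.5]; adjacent SNPs within a block correlate
    at ``ld_decay`` with geometric decay over distance.  A trailing partial
    block is kept with a warning.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    m, bs = config.m_snps, config.ld_block_size
    if m % bs:
        warnings.warn(f"m_snps={m} not a multiple of block size {bs}; last block truncated")
    bounds = [(s, min(s + bs, m)) for s in range(0, m, bs)]
    mafs = rng.uniform(0.05, 0.5, size=m)
    is_amb = rng.random(m) < config.ambiguous_fraction
    pair_idx = rng.integers(0, 8, size=m)
    amb_idx = rng.integers(0, 4, size=m)

    geno = np.empty((config.n_ref, m))
    for s, e in bounds:
        k = e - s
        idx = np.arange(k)
        R = config.ld_decay ** np.abs(idx[:, None] - idx[None, :])
        L = np.linalg.cholesky(R)
        latent = rng.standard_normal((config.n_ref, k)) @ L.T
        scale = np.sqrt(2 * mafs[s:e] * (1 - mafs[s:e]))
        geno[:, s:e] = 2 * mafs[s:e] + latent * scale

    variants = []
    for j in range(m):
        a1, a2 = (_AMBIGUOUS_PAIRS[amb_idx[j]] if is_amb[j]
                  else _NONAMBIGUOUS_PAIRS[pair_idx[j]])
        variants.append(VariantRecord(
            snp_id=f"rs{j + 1}", chrom="1", pos=1 + j * 1000,
            a1=a1, a2=a2, maf=float(mafs[j]), info=1.0))
    return LDPanel(variants=variants, genotypes=geno, block_bounds=bounds)


def reference_from_panel(panel: LDPanel) -> pd.DataFrame:
    """Reference table (SNP, A1, A2, MAF) for harmonization."""
    return panel.variants_frame()[["SNP", "A1", "A2", "MAF"]]


def _sumstats_frame(panel, z, n_cases, n_controls, info, rng):
    se = 1.0 / np.sqrt(n_cases + n_controls)
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 5e-324)
    vf = panel.variants_frame()
    return pd.DataFrame({
        "SNP": vf["SNP"], "CHR": vf["CHR"], "BP": vf["BP"],
        "A1": vf["A1"], "A2": vf["A2"],
        "BETA": z * se, "SE": se, "Z": z, "P": p,
        "N_CAS": n_cases, "N_CON": n_controls,
        "MAF": vf["MAF"], "INFO": info,
    })[CANONICAL_COLUMNS]


def simulate_bivariate_sumstats(
    panel: LDPanel,
    config: SimulationConfig,
    causal_weights: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate paired GWAS summary statistics with known h2 / rg.

    Per-SNP causal effects are bivariate normal with variances
    ``h2_k * w_j / sum(w)`` and cross-covariance ``rg * sqrt(v1 v2)``;
    ``causal_weights`` (default uniform) plant per-category enrichment.
    Sample overlap adds a constant cross-trait noise correlation
    ``n_overlap / sqrt(N1 N2)``.  INFO is drawn from U[0.85, 1] per trait
    so harmonization has work to do.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    m = panel.m
    w = np.ones(m) if causal_weights is None else np.asarray(causal_weights, dtype=float)
    if w.shape != (m,) or (w < 0).any() or w.sum() <= 0:
        raise ValueError("causal_weights must be non-negative with positive sum")
    v1 = config.h2_1 * w / w.sum()
    v2 = config.h2_2 * w / w.sum()

    x1 = rng.standard_normal(m)
    x2 = rng.standard_normal(m)
    beta1 = np.sqrt(v1) * x1
    beta2 = np.sqrt(v2) * (config.rg * x1 + np.sqrt(1 - config.rg**2) * x2)

    n1, n2 = config.n1, config.n2
    rho_n = config.n_overlap / np.sqrt(n1 * n2)
    if rho_n > 1:
        raise ValueError("n_overlap exceeds sqrt(N1*N2)")
    z1 = np.empty(m)
    z2 = np.empty(m)
    for b, (s, e) in enumerate(panel.block_bounds):
        L = panel.block_chol(b)
        R = L @ L.T
        u1 = rng.standard_normal(e - s)
        u2 = rng.standard_normal(e - s)
        e1 = L @ u1
        e2 = L @ (rho_n * u1 + np.sqrt(1 - rho_n**2) * u2)
        z1[s:e] = np.sqrt(n1) * (R @ beta1[s:e]) + e1
        z2[s:e] = np.sqrt(n2) * (R @ beta2[s:e]) + e2

    info1 = rng.uniform(0.85, 1.0, size=m)
    info2 = rng.uniform(0.85, 1.0, size=m)
    df1 = _sumstats_frame(panel, z1, config.n1_cases, config.n1_controls, info1, rng)
    df2 = _sumstats_frame(panel, z2, config.n2_cases, config.n2_controls, info2, rng)
    rho_g = config.rg * np.sqrt(config.h2_1 * config.h2_2)
    truth = {
        "h2_1": config.h2_1, "h2_2": config.h2_2, "rg": config.rg,
        "rho_g": rho_g, "rho_n": rho_n, "n1": n1, "n2": n2, "m_snps": m,
        "beta1": beta1, "beta2": beta2,
    }
    return df1, df2, truth


@dataclass
class EqtlLocusSim:
    eqtl: list[EqtlRecord]
    gwas: pd.DataFrame
    ld: np.ndarray
    snp_ids: list[str]
    truth: dict


def simulate_eqtl_locus(
    panel: LDPanel,
    scenario: str,
    b_zx: float = 0.5,
    b_xy: float = 0.2,
    n_eqtl: int = 10_000,
    n_gwas: int = 20_000,
    block: int = 0,
    causal: int | None = None,
    linkage_r2: float = 0.5,
    seed: int = 0,
    probe: str = "probe1",
    gene: str = "GENE1",
) -> EqtlLocusSim:
    """Simulate one cis region under pleiotropy, linkage, or the null.

    pleiotropy: a single causal SNP drives both expression and trait, so
    the per-SNP ``b_zy/b_zx`` ratio is constant at ``b_xy``.  linkage: a
    second causal SNP with r2 about ``linkage_r2`` to the first drives the
    trait instead.  null: expression signal only.
    """
    if scenario not in ("pleiotropy", "linkage", "null"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    s, e = panel.block_bounds[block]
    k = e - s
    R = panel.block_corr(block)
    L = panel.block_chol(block)
    c = (k // 2) if causal is None else causal
    if not 0 <= c < k:
        raise ValueError("causal index outside block")
    if panel.variants[s + c].maf in (0.0, None):
        raise ValueError("causal SNP is monomorphic")

    se_zx = np.full(k, 1.0 / np.sqrt(n_eqtl))
    se_zy = np.full(k, 1.0 / np.sqrt(n_gwas))
    bx_marg = R[:, c] * b_zx
    bhat_zx = bx_marg + (L @ rng.standard_normal(k)) * se_zx[0]

    c2 = c
    if scenario == "pleiotropy":
        by_marg = R[:, c] * (b_zx * b_xy)
    elif scenario == "null":
        by_marg = np.zeros(k)
    else:
        r2_to_c = R[:, c] ** 2
        candidates = np.flatnonzero(np.arange(k) != c)
        c2 = int(candidates[np.argmin(np.abs(r2_to_c[candidates] - linkage_r2))])
        by_marg = R[:, c2] * (b_zx * b_xy)
    bhat_zy = by_marg + (L @ rng.standard_normal(k)) * se_zy[0]

    snp_ids = [panel.variants[s + j].snp_id for j in range(k)]
    p_zx = np.maximum(2.0 * stats.norm.sf(np.abs(bhat_zx / se_zx)), 5e-324)
    eqtl = [EqtlRecord(probe=probe, gene=gene, snp_id=snp_ids[j],
                       b_zx=float(bhat_zx[j]), se_zx=float(se_zx[j]),
                       p_zx=float(p_zx[j])) for j in range(k)]
    z = bhat_zy / se_zy
    vf = panel.variants_frame().iloc[s:e].reset_index(drop=True)
    gwas = pd.DataFrame({
        "SNP": snp_ids, "CHR": vf["CHR"], "BP": vf["BP"],
        "A1": vf["A1"], "A2": vf["A2"],
        "BETA": bhat_zy, "SE": se_zy, "Z": z,
        "P": np.maximum(2.0 * stats.norm.sf(np.abs(z)), 5e-324),
        "N_CAS": n_gwas // 2, "N_CON": n_gwas - n_gwas // 2,
        "MAF": vf["MAF"], "INFO": 1.0,
    })[CANONICAL_COLUMNS]
    truth = {"scenario": scenario, "causal": snp_ids[c], "causal2": snp_ids[c2],
             "b_zx": b_zx, "b_xy": b_xy if scenario != "null" else 0.0,
             "r2_causals": float(R[c, c2] ** 2)}
    return EqtlLocusSim(eqtl=eqtl, gwas=gwas, ld=R, snp_ids=snp_ids, truth=truth)


def make_peak_fixture(
    panel: LDPanel,
    enriched_set: Sequence[str],
    coverage_background: float,
    seed: int = 0,
    half_width: int = 0,
) -> pd.DataFrame:
    """BED-style intervals (0-based half-open) covering planted SNPs.

    Every SNP in ``enriched_set`` gets an interval; each remaining SNP is
    covered independently with probability ``coverage_background``.
    """
    if not 0.0 <= coverage_background < 1.0:
        raise ValueError("coverage_background must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    enriched = set(enriched_set)
    unknown = enriched - set(panel.snp_ids)
    if unknown:
        raise ValueError(f"enriched SNPs not in panel: {sorted(unknown)[:5]}")
    rows = []
    for v in panel.variants:
        if v.snp_id in enriched or rng.random() < coverage_background:
            start = max(0, v.pos - 1 - half_width)
            rows.append((v.chrom, start, v.pos + half_width))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class Table1Row:
    """One variant row of the packaged risk-locus table."""

    locus: str
    discovery: str
    variant: str
    role: str  # sentinel | correlated
    position: int
    risk_allele_cll: str | None
    risk_allele_mm: str | None
    or_cll: float | None
    or_mm: float | None
    p_cll: float | None
    p_mm: float | None
    p_cll_str: str | None = None
    p_mm_str: str | None = None


@dataclass
class Table1Fixture:
    """Packaged transcription of the published risk-locus table."""

    rows: list[Table1Row]

    VALID_DISCOVERY = ("MM", "CLL", "MM & CLL")

    def __post_init__(self) -> None:
        for row in self.rows:
            if row.discovery not in self.VALID_DISCOVERY:
                raise ValueError(f"bad discovery label {row.discovery!r}")
        if len(self.loci) != 10:
            raise ValueError(f"expected 10 loci, got {len(self.loci)}")

    @property
    def loci(self) -> list[str]:
        out = []
        for row in self.rows:
            if row.locus not in out:
                out.append(row.locus)
        return out

    def rows_for(self, locus: str) -> list[Table1Row]:
        return [r for r in self.rows if r.locus == locus]

    def discovery_of(self, locus: str) -> str:
        labels = {r.discovery for r in self.rows_for(locus)}
        if len(labels) != 1:
            raise ValueError(f"conflicting discovery labels at {locus}")
        return labels.pop()

    def p_lookup(self, trait: str) -> dict[str, float]:
        """SNP id -> p-value in the given trait ('CLL' or 'MM'); absent cells skipped."""
        attr = {"CLL": "p_cll", "MM": "p_mm"}[trait]
        return {r.variant: getattr(r, attr) for r in self.rows
                if getattr(r, attr) is not None}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def table1_fixture() -> Table1Fixture:
    """Load the packaged risk-locus table ('-' cells become None)."""
    path = resources.files("crosstrait").joinpath("data/risk_loci_table.tsv")
    with resources.as_file(path) as fp:
        df = pd.read_csv(fp, sep="\t", dtype=str)

    def opt(val, cast=float):
        return None if val is None or val == "-" or pd.isna(val) else cast(val)

    rows = []
    for r in df.itertuples(index=False):
        rows.append(Table1Row(
            locus=r.locus, discovery=r.discovery, variant=r.variant, role=r.role,
            position=int(r.position),
            risk_allele_cll=opt(r.risk_allele_cll, str),
            risk_allele_mm=opt(r.risk_allele_mm, str),
            or_cll=opt(r.or_cll), or_mm=opt(r.or_mm),
            p_cll=opt(r.p_cll), p_mm=opt(r.p_mm),
            p_cll_str=opt(r.p_cll, str), p_mm_str=opt(r.p_mm, str)))
    return Table1Fixture(rows=rows)
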