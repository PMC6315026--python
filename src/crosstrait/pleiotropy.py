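"""Correlated-variant sets around risk loci and the region-wide cross-trait scan.

A risk locus is represented by its sentinel SNP plus every panel variant in
strong LD with it (the associated variant set, AVS).  The scan asks, for
each locus discovered in one trait, whether any member variant associates
with the other trait at region-wide significance after Bonferroni
correction over the discovery loci; a locus whose variants reach
genome-wide significance in both traits is pleiotropic regardless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import LDPanel, Table1Fixture

__all__ = [
    "AVS",
    "LocusResult",
    "bonferroni_threshold",
    "em_haplotype_freqs",
    "dprime_from_genotypes",
    "build_avs",
    "region_wide_scan",
    "classify_pleiotropic",
    "fixture_loci",
    "scan_table1",
    "GENOME_WIDE_P",
]

GENOME_WIDE_P = 5e-8


@dataclass
class AVS:
    """A sentinel plus its correlated-variant set defining one risk locus."""

    locus: str
    sentinel_id: str
    members: pd.DataFrame  # columns: SNP, CHR, BP, r2, dprime
    discovery: str | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.sentinel_id not in set(self.members["SNP"]):
            raise ValueError(f"{self.locus}: sentinel not among members")

    @property
    def member_ids(self) -> list[str]:
        return self.members["SNP"].tolist()

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SimpleLocus:
    """Locus with explicit member list (no panel backing)."""

    locus: str
    discovery: str | None
    member_ids: list[str]


@dataclass
class LocusResult:
    locus: str
    discovery: str | None
    best_snp: str | None
    best_p: float | None
    threshold: float
    passes: bool
    genome_wide_both: bool | None = None
    n_absent: int = 0
    untestable: bool = False


def bonferroni_threshold(alpha: float, n_discovery_loci: int) -> float:
    """Region-wide significance threshold alpha / number of discovery loci."""
    if n_discovery_loci < 1:
        raise ValueError("n_discovery_loci must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / n_discovery_loci


def em_haplotype_freqs(
    g1: np.ndarray, g2: np.ndarray, max_iter: int = 200, tol: float = 1e-12
) -> np.ndarray:
    """EM haplotype frequencies [p00, p01, p10, p11] for two biallelic SNPs.

    Input is 0/1/2 alt-allele counts per individual (NaN allowed, pairwise
    deleted).  Only the double-heterozygote cell is phase-ambiguous; the EM
    splits it between cis and trans configurations.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(g1) | np.isnan(g2))
    g1, g2 = g1[ok].astype(int), g2[ok].astype(int)
    if g1.size == 0:
        raise ValueError("no complete genotype pairs")
    n = np.zeros((3, 3))
    for a, b in zip(g1, g2):
        n[a, b] += 1
    total = 2.0 * g1.size
    c00 = 2 * n[0, 0] + n[0, 1] + n[1, 0]
    c01 = 2 * n[0, 2] + n[0, 1] + n[1, 2]
    c10 = 2 * n[2, 0] + n[1, 0] + n[2, 1]
    c11 = 2 * n[2, 2] + n[2, 1] + n[1, 2]
    dh = n[1, 1]
    p = np.full(4, 0.25)
    for _ in range(max_iter):
        denom = p[0] * p[3] + p[1] * p[2]
        x = 0.5 if denom == 0 else p[0] * p[3] / denom
        new = np.array([
            (c00 + x * dh) / total,
            (c01 + (1 - x) * dh) / total,
            (c10 + (1 - x) * dh) / total,
            (c11 + x * dh) / total,
        ])
        if np.max(np.abs(new - p)) < tol:
            p = new
            break
        p = new
    return p


def dprime_from_genotypes(g1: np.ndarray, g2: np.ndarray) -> float:
    """Normalized disequilibrium D' from EM haplotype frequencies."""
    p = em_haplotype_freqs(g1, g2)
    pa = p[2] + p[3]
    pb = p[1] + p[3]
    d = p[3] - pa * pb
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    if dmax == 0:
        return 0.0
    return float(abs(d) / dmax)


def build_avs(
    sentinel: str,
    panel: LDPanel,
    r2_threshold: float = 0.8,
    dprime_threshold: float | None = None,
    window_bp: int = 500_000,
    locus: str | None = None,
    discovery: str | None = None,
) -> AVS:
    """Collect panel variants correlated with a sentinel into an AVS.

    Membership requires dosage (composite) r2 above ``r2_threshold`` within
    ``window_bp`` of the sentinel, and D' (EM haplotype frequencies on hard
    calls) above ``dprime_threshold`` when given.  The sentinel is always a
    member.
    """
    ids = panel.snp_ids
    try:
        s_idx = ids.index(sentinel)
    except ValueError:
        raise ValueError(f"sentinel {sentinel} absent from panel") from None
    pos = panel.positions
    s_pos = pos[s_idx]
    cand = np.flatnonzero(np.abs(pos - s_pos) <= window_bp)
    X = panel.genotypes
    hard = None
    s_col = X[:, s_idx]
    s_std = s_col.std()
    rows = []
    for j in cand:
        if j == s_idx:
            rows.append((ids[j], panel.variants[j].chrom, int(pos[j]), 1.0, 1.0))
            continue
        col = X[:, j]
        sd = col.std()
        if sd == 0 or s_std == 0:
            continue
        r = float(np.corrcoef(s_col, col)[0, 1])
        r2 = r * r
        if r2 <= r2_threshold:
            continue
        if hard is None:
            hard = panel.hard_calls()
        dp = dprime_from_genotypes(hard[:, s_idx], hard[:, j])
        if dprime_threshold is not None and dp <= dprime_threshold:
            continue
        rows.append((ids[j], panel.variants[j].chrom, int(pos[j]), r2, dp))
    members = pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "r2", "dprime"])
    return AVS(locus=locus or sentinel, sentinel_id=sentinel, members=members,
               discovery=discovery, maf=panel.variants[s_idx].maf)


def region_wide_scan(
    loci: Sequence,
    other_trait: Mapping[str, float],
    n_discovery_loci: int,
    alpha: float = 0.05,
    discovery_trait: Mapping[str, float] | None = None,
    gw_threshold: float = GENOME_WIDE_P,
) -> list[LocusResult]:
    """Test each locus for association in the other trait.

    A locus passes when the minimum other-trait p-value over its resolvable
    members falls below ``alpha / n_discovery_loci``.  Members absent from
    the lookup are skipped with a count; a locus with no resolvable member
    is flagged untestable rather than counted as pass or fail.  When the
    discovery-trait lookup is supplied, ``genome_wide_both`` flags loci
    with some member below ``gw_threshold`` in both traits.
    """
    threshold = bonferroni_threshold(alpha, n_discovery_loci)
    results = []
    for loc in loci:
        member_ids = list(loc.member_ids)
        resolvable = [(s, other_trait[s]) for s in member_ids if s in other_trait]
        n_absent = len(member_ids) - len(resolvable)
        gw_both = None
        if discovery_trait is not None:
            gw_both = any(
                s in other_trait and s in discovery_trait
                and other_trait[s] < gw_threshold
                and discovery_trait[s] < gw_threshold
                for s in member_ids
            )
        if not resolvable:
            results.append(LocusResult(
                locus=loc.locus, discovery=getattr(loc, "discovery", None),
                best_snp=None, best_p=None, threshold=threshold, passes=False,
                genome_wide_both=gw_both, n_absent=n_absent, untestable=True))
            continue
        best_snp, best_p = min(resolvable, key=lambda t: t[1])
        results.append(LocusResult(
            locus=loc.locus, discovery=getattr(loc, "discovery", None),
            best_snp=best_snp, best_p=best_p, threshold=threshold,
            passes=best_p < threshold, genome_wide_both=gw_both,
            n_absent=n_absent))
    return results


def classify_pleiotropic(
    results_a: Sequence[LocusResult],
    results_b: Sequence[LocusResult],
    gw_threshold: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """Combine both scan directions into the pleiotropic-locus table.

    The pleiotropic set is the union of loci passing either directional
    scan and loci genome-wide significant in both traits, deduplicated by
    locus name.
    """
    discovery_by_locus: dict[str, str | None] = {}
    rows: dict[str, dict] = {}
    for res in list(results_a) + list(results_b):
        if res.locus in discovery_by_locus:
            if discovery_by_locus[res.locus] != res.discovery:
                raise ValueError(
                    f"locus {res.locus}: conflicting discovery labels "
                    f"{discovery_by_locus[res.locus]!r} vs {res.discovery!r}")
        else:
            discovery_by_locus[res.locus] = res.discovery
        row = rows.setdefault(res.locus, {
            "locus": res.locus, "discovery": res.discovery,
            "passes_scan": False, "genome_wide_both": False,
            "best_p": None, "best_snp": None,
        })
        row["passes_scan"] = row["passes_scan"] or res.passes
        row["genome_wide_both"] = row["genome_wide_both"] or bool(res.genome_wide_both)
        if res.best_p is not None and (row["best_p"] is None or res.best_p < row["best_p"]):
            row["best_p"], row["best_snp"] = res.best_p, res.best_snp
    table = pd.DataFrame(
        [r for r in rows.values() if r["passes_scan"] or r["genome_wide_both"]],
        columns=["locus", "discovery", "passes_scan", "genome_wide_both",
                 "best_p", "best_snp"])
    return table.reset_index(drop=True)


def fixture_loci(fixture: Table1Fixture, discovery: str) -> list[SimpleLocus]:
    """Loci from the packaged table whose discovery label is exactly ``discovery``.

    Loci labelled for both traits are handled by the genome-wide-both route
    rather than either directional scan.
    """
    out = []
    for locus in fixture.loci:
        if fixture.discovery_of(locus) == discovery:
            out.append(SimpleLocus(
                locus=locus, discovery=discovery,
                member_ids=[r.variant for r in fixture.rows_for(locus)]))
    return out


def scan_table1(
    fixture: Table1Fixture,
    alpha: float = 0.05,
    n_cll_loci: int = 45,
    n_mm_loci: int = 23,
) -> dict:
    """Run both directional scans plus the genome-wide-both check on the fixture.

    Returns per-direction results, the combined pleiotropic table and the
    headline counts.
    """
    p_cll = fixture.p_lookup("CLL")
    p_mm = fixture.p_lookup("MM")
    cll_in_mm = region_wide_scan(
        fixture_loci(fixture, "CLL"), other_trait=p_mm,
        n_discovery_loci=n_cll_loci, alpha=alpha, discovery_trait=p_cll)
    mm_in_cll = region_wide_scan(
        fixture_loci(fixture, "MM"), other_trait=p_cll,
        n_discovery_loci=n_mm_loci, alpha=alpha, discovery_trait=p_mm)
    # dual-discovery loci only count through the genome-wide-both route
    both_results = []
    for locus in fixture.loci:
        if fixture.discovery_of(locus) != "MM & CLL":
            continue
        members = [r.variant for r in fixture.rows_for(locus)]
        gw_both = any(
            s in p_cll and s in p_mm
            and p_cll[s] < GENOME_WIDE_P and p_mm[s] < GENOME_WIDE_P
            for s in members
        )
        best = min(((s, p_mm[s]) for s in members if s in p_mm),
                   key=lambda t: t[1], default=(None, None))
        both_results.append(LocusResult(
            locus=locus, discovery="MM & CLL", best_snp=best[0], best_p=best[1],
            threshold=0.0, passes=False, genome_wide_both=gw_both))
    combined = classify_pleiotropic(cll_in_mm + both_results, mm_in_cll)
    return {
        "cll_in_mm": cll_in_mm,
        "mm_in_cll": mm_in_cll,
        "n_cll_pass": sum(r.passes for r in cll_in_mm),
        "n_mm_pass": sum(r.passes for r in mm_in_cll),
        "n_genome_wide_both": int(combined["genome_wide_both"].sum()),
        "combined": combined,
        "n_pleiotropic": len(combined),
        "threshold_cll": bonferroni_threshold(alpha, n_cll_loci),
        "threshold_mm": bonferroni_threshold(alpha, n_mm_loci),
    }
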