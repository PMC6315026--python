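"""Reading, validation, harmonization and QC of GWAS summary statistics.

The canonical on-disk format is a tab/whitespace separated table with header

    SNP CHR BP A1 A2 BETA SE Z P N_CAS N_CON MAF INFO

``A1`` is the effect allele.  Foreign headers are accommodated through a
*dialect*: a mapping from canonical column names to the names used in the
file.  Harmonization aligns two studies to a shared reference panel,
removing indels, poorly imputed or rare variants, strand-ambiguous SNPs and
SNPs whose alleles cannot be reconciled with the reference, and sign-flips
effect sizes where the study effect allele is the reference other allele.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "CANONICAL_COLUMNS",
    "DEFAULT_HLA_REGION",
    "REMOVAL_REASONS",
    "ConfigurationError",
    "DegenerateInputError",
    "HarmonizationError",
    "VariantRecord",
    "SummaryStatRecord",
    "QCReport",
    "InflationResult",
    "ReadResult",
    "read_sumstats",
    "write_sumstats",
    "records_to_frame",
    "frame_to_records",
    "harmonize_pair",
    "qc_genotypes",
    "hwe_exact_test",
    "genomic_inflation",
]

CANONICAL_COLUMNS = [
    "SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "Z", "P",
    "N_CAS", "N_CON", "MAF", "INFO",
]

#: Mandatory identity columns; statistics may be derived (Z from BETA/SE).
MANDATORY_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2"]

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))

#: HLA exclusion interval, 1-based inclusive (chrom, start, end).
DEFAULT_HLA_REGION = ("6", 25_000_000, 34_000_000)

#: Fixed precedence of removal reasons; each SNP is assigned the first that
#: triggers, so reason counts plus the retained count total the input count.
REMOVAL_REASONS = (
    "parse",
    "indel",
    "info",
    "maf",
    "not_in_reference",
    "reference_maf",
    "strand_ambiguous",
    "allele_mismatch",
    "hla",
    "not_in_both",
)

# smallest positive double; p-values derived from extreme Z are clipped here
_TINY_P = 5e-324


class ConfigurationError(ValueError):
    """Input table or dialect does not satisfy the declared contract."""


class DegenerateInputError(ValueError):
    """All rows/individuals were removed; nothing left to analyse."""


class HarmonizationError(ValueError):
    """No SNPs survive harmonization."""


def _p_from_z(z: float) -> float:
    return max(float(2.0 * stats.norm.sf(abs(z))), _TINY_P)


def _neglog10(p: float) -> float:
    return -math.log10(p) if p > 0 else math.inf


@dataclass
class VariantRecord:
    """A single variant: identity, alleles and per-SNP annotations."""

    snp_id: str
    chrom: str
    pos: int
    a1: str
    a2: str
    maf: float | None = None
    info: float | None = None

    def __post_init__(self) -> None:
        self.snp_id = str(self.snp_id)
        self.chrom = str(self.chrom).removeprefix("chr")
        self.pos = int(self.pos)
        self.a1 = str(self.a1).upper()
        self.a2 = str(self.a2).upper()
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1")
        if self.a1 == self.a2:
            raise ValueError(f"{self.snp_id}: identical alleles {self.a1}")
        if self.maf is not None:
            self.maf = float(self.maf)
            if not 0.0 <= self.maf <= 0.5:
                raise ValueError(f"{self.snp_id}: MAF {self.maf} outside [0, 0.5]")
        if self.info is not None:
            self.info = float(self.info)
            if not 0.0 <= self.info <= 1.0:
                raise ValueError(f"{self.snp_id}: INFO {self.info} outside [0, 1]")

    @property
    def is_indel(self) -> bool:
        """Multi-base or non-ACGT alleles are flagged as indels, not errors."""
        return not (self.a1 in _BASES and self.a2 in _BASES)

    @property
    def is_strand_ambiguous(self) -> bool:
        return frozenset((self.a1, self.a2)) in _AMBIGUOUS_PAIRS

    def in_region(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == str(chrom).removeprefix("chr") and start <= self.pos <= end


@dataclass
class SummaryStatRecord:
    """One harmonized per-SNP association result for one trait.

    Missing ``z`` is derived from ``beta/se`` and missing ``p`` from ``z``
    under the two-sided normal.  When redundantly supplied the fields must
    agree: ``z`` with ``beta/se`` to 1e-6 and ``p`` with the z-implied
    p-value to 1e-6 on the -log10 scale.
    """

    variant: VariantRecord
    beta: float | None = None
    se: float | None = None
    z: float | None = None
    p: float | None = None
    n_cases: int = 0
    n_controls: int = 0

    def __post_init__(self) -> None:
        if self.se is not None and self.se <= 0:
            raise ValueError(f"{self.variant.snp_id}: SE must be > 0")
        if self.z is None:
            if self.beta is None or self.se is None:
                raise ValueError(f"{self.variant.snp_id}: need Z or BETA+SE")
            self.z = self.beta / self.se
        elif self.beta is not None and self.se is not None:
            if not math.isclose(self.z, self.beta / self.se, rel_tol=1e-6, abs_tol=1e-6):
                raise ValueError(
                    f"{self.variant.snp_id}: Z={self.z} inconsistent with "
                    f"BETA/SE={self.beta / self.se}"
                )
        self.z = float(self.z)
        if self.p is None:
            self.p = _p_from_z(self.z)
        else:
            self.p = float(self.p)
            if not 0.0 < self.p <= 1.0:
                raise ValueError(f"{self.variant.snp_id}: P={self.p} outside (0, 1]")
            implied = _p_from_z(self.z)
            if abs(_neglog10(self.p) - _neglog10(implied)) > 1e-6:
                raise ValueError(
                    f"{self.variant.snp_id}: P={self.p} inconsistent with Z={self.z}"
                )
        self.n_cases = int(self.n_cases)
        self.n_controls = int(self.n_controls)

    @property
    def chi2(self) -> float:
        return self.z * self.z


@dataclass
class QCReport:
    """Machine-readable record of what a filtering step removed and why."""

    n_input: int
    n_removed_by_reason: dict[str, int] = field(default_factory=dict)
    retained: set[str] = field(default_factory=set)
    removed_by_reason: dict[str, list[str]] = field(default_factory=dict)
    n_individuals_removed: int = 0

    def validate(self) -> None:
        total = sum(self.n_removed_by_reason.values()) + len(self.retained)
        if total != self.n_input:
            raise AssertionError(
                f"QCReport inconsistent: {total} accounted for, {self.n_input} input"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed_{k}", v) for k, v in self.n_removed_by_reason.items()]
        rows.append(("retained", len(self.retained)))
        return pd.DataFrame(rows, columns=["key", "count"])

    def log_lines(self) -> list[str]:
        lines = [f"{self.n_input} SNPs read"]
        for reason, n in self.n_removed_by_reason.items():
            if n:
                lines.append(f"removed {n} SNPs: {reason}")
        lines.append(f"{len(self.retained)} SNPs retained")
        return lines


@dataclass
class InflationResult:
    lambda_gc: float
    lambda_1000: float
    n_snps_used: int
    warnings: list[str] = field(default_factory=list)


class ReadResult(list):
    """List of records plus a log of rows that could not be parsed."""

    def __init__(self, records: Iterable[SummaryStatRecord] = ()):
        super().__init__(records)
        self.skipped: list[tuple[int, str, str]] = []


def _resolve_dialect(columns: Sequence[str], dialect: Mapping[str, str] | None):
    """Map canonical names to actual column names, case-insensitively."""
    dialect = dict(dialect or {})
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for canon in CANONICAL_COLUMNS:
        actual = dialect.get(canon, canon)
        if actual in columns:
            resolved[canon] = actual
        elif actual.lower() in lower:
            resolved[canon] = lower[actual.lower()]
        elif canon in dialect:
            raise ConfigurationError(f"required column {actual!r} ({canon}) missing")
    return resolved


def read_sumstats(path, dialect: Mapping[str, str] | None = None) -> ReadResult:
    """Read a summary-statistics table into validated records.

    Rows whose mandatory fields cannot be parsed, or whose redundant
    statistics disagree beyond 1e-4 on the -log10 p scale, are recorded on
    the result's ``skipped`` attribute rather than silently dropped.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    resolved = _resolve_dialect(df.columns, dialect)
    for canon in MANDATORY_COLUMNS:
        if canon not in resolved:
            raise ConfigurationError(f"mandatory column {canon!r} missing from header")
    if "Z" not in resolved and not ("BETA" in resolved and "SE" in resolved):
        raise ConfigurationError("need either Z or BETA+SE columns")

    def get(row, canon, cast=float):
        if canon not in resolved:
            return None
        raw = row[resolved[canon]]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw in ("", "NA", "-", "."):
            return None
        return cast(raw)

    out = ReadResult()
    for i, row in df.iterrows():
        try:
            variant = VariantRecord(
                snp_id=row[resolved["SNP"]],
                chrom=row[resolved["CHR"]],
                pos=int(float(row[resolved["BP"]])),
                a1=row[resolved["A1"]],
                a2=row[resolved["A2"]],
                maf=get(row, "MAF"),
                info=get(row, "INFO"),
            )
            beta, se, z, p = (get(row, c) for c in ("BETA", "SE", "Z", "P"))
            if p is not None and z is not None:
                implied = _p_from_z(z)
                if abs(_neglog10(p) - _neglog10(implied)) > 1e-4:
                    raise ValueError(f"P={p} inconsistent with Z={z}")
            record = SummaryStatRecord(
                variant=variant, beta=beta, se=se, z=z, p=p,
                n_cases=get(row, "N_CAS", int) or 0,
                n_controls=get(row, "N_CON", int) or 0,
            )
        except (ValueError, KeyError) as exc:
            reason = "inconsistent_stats" if "inconsistent" in str(exc) else "parse"
            out.skipped.append((int(i), reason, str(exc)))
            continue
        out.append(record)
    if out.skipped:
        warnings.warn(f"{len(out.skipped)} rows skipped while reading {path}")
    return out


def records_to_frame(records: Iterable[SummaryStatRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        v = r.variant
        rows.append((v.snp_id, v.chrom, v.pos, v.a1, v.a2, r.beta, r.se,
                     r.z, r.p, r.n_cases, r.n_controls, v.maf, v.info))
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[SummaryStatRecord]:
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def opt(key):
            val = d.get(key)
            return None if val is None or (isinstance(val, float) and math.isnan(val)) else val

        variant = VariantRecord(d["SNP"], d["CHR"], d["BP"], d["A1"], d["A2"],
                                maf=opt("MAF"), info=opt("INFO"))
        records.append(SummaryStatRecord(
            variant=variant, beta=opt("BETA"), se=opt("SE"), z=opt("Z"), p=opt("P"),
            n_cases=int(d.get("N_CAS") or 0), n_controls=int(d.get("N_CON") or 0)))
    return records


def write_sumstats(data, path) -> None:
    df = data if isinstance(data, pd.DataFrame) else records_to_frame(data)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data.copy()
    return records_to_frame(data)


def _reference_frame(reference) -> pd.DataFrame:
    if isinstance(reference, pd.DataFrame):
        ref = reference.copy()
    else:
        rows = [(v.snp_id, v.a1, v.a2, v.maf) for v in reference]
        ref = pd.DataFrame(rows, columns=["SNP", "A1", "A2", "MAF"])
    ref["A1"] = ref["A1"].astype(str).str.upper()
    ref["A2"] = ref["A2"].astype(str).str.upper()
    return ref.drop_duplicates("SNP").set_index("SNP")


def _allele_relation(a1, a2, ra1, ra2) -> str | None:
    """How study alleles relate to the reference pair, or None if irreconcilable.

    A/T and C/G pairs must be removed beforehand, so strand flips are
    unambiguous here.
    """
    if (a1, a2) == (ra1, ra2):
        return "match"
    if (a1, a2) == (ra2, ra1):
        return "swap"
    try:
        f1, f2 = _COMPLEMENT[a1], _COMPLEMENT[a2]
    except KeyError:
        return None
    if (f1, f2) == (ra1, ra2):
        return "flip"
    if (f1, f2) == (ra2, ra1):
        return "flip_swap"
    return None


def harmonize_pair(
    ss_a,
    ss_b,
    reference,
    hla_region: tuple[str, int, int] | None = DEFAULT_HLA_REGION,
    info_min: float = 0.9,
    maf_min: float = 0.01,
    ref_maf_min: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, QCReport]:
    """Harmonize two studies to a common reference panel.

    Retained SNPs satisfy INFO > ``info_min``, study MAF > ``maf_min``,
    presence in the reference with reference MAF > ``ref_maf_min``,
    single-base non-ambiguous alleles matching the reference pair up to
    swap and/or strand flip, position outside the HLA interval, and
    presence in both traits.  Allele-swapped records have BETA and Z
    sign-flipped to the reference effect allele; |Z| is never changed.
    Each removed SNP is assigned exactly one reason, following the fixed
    precedence in :data:`REMOVAL_REASONS`.
    """
    frames = {"a": _as_frame(ss_a), "b": _as_frame(ss_b)}
    ref = _reference_frame(reference)
    report = QCReport(n_input=0)
    removed: dict[str, str] = {}  # snp -> reason (first triggered)

    for key, df in frames.items():
        dup = df["SNP"].duplicated()
        if dup.any():
            warnings.warn(f"{int(dup.sum())} duplicate SNP ids dropped from trait {key}")
            for snp in df.loc[dup, "SNP"]:
                removed.setdefault(snp, "parse")
            frames[key] = df[~dup].copy()

    all_ids: list[str] = []
    seen = set()
    for df in frames.values():
        for snp in df["SNP"]:
            if snp not in seen:
                seen.add(snp)
                all_ids.append(snp)
    report.n_input = len(all_ids)

    def mark(ids: Iterable[str], reason: str) -> None:
        for snp in ids:
            removed.setdefault(snp, reason)

    for key, df in frames.items():
        df["A1"] = df["A1"].astype(str).str.upper()
        df["A2"] = df["A2"].astype(str).str.upper()
        a1, a2 = df["A1"], df["A2"]
        single = a1.isin(_BASES) & a2.isin(_BASES)
        mark(df.loc[~single, "SNP"], "indel")
        if "INFO" in df.columns and df["INFO"].notna().any():
            bad = df["INFO"].notna() & (df["INFO"] <= info_min)
            mark(df.loc[bad, "SNP"], "info")
        if "MAF" in df.columns and df["MAF"].notna().any():
            bad = df["MAF"].notna() & (df["MAF"] <= maf_min)
            mark(df.loc[bad, "SNP"], "maf")

    mark([s for s in all_ids if s not in ref.index], "not_in_reference")
    in_ref = ref.loc[[s for s in all_ids if s in ref.index]]
    if "MAF" in in_ref.columns:
        mark(in_ref.index[in_ref["MAF"] <= ref_maf_min], "reference_maf")
    ambiguous = in_ref.index[[
        frozenset((x, y)) in _AMBIGUOUS_PAIRS for x, y in zip(in_ref["A1"], in_ref["A2"])
    ]]
    mark(ambiguous, "strand_ambiguous")
    for df in frames.values():
        amb = [frozenset((x, y)) in _AMBIGUOUS_PAIRS for x, y in zip(df["A1"], df["A2"])]
        mark(df.loc[amb, "SNP"], "strand_ambiguous")

    relations: dict[str, dict[str, str]] = {"a": {}, "b": {}}
    for key, df in frames.items():
        for snp, a1, a2 in zip(df["SNP"], df["A1"], df["A2"]):
            if snp in removed or snp not in ref.index:
                continue
            rel = _allele_relation(a1, a2, ref.at[snp, "A1"], ref.at[snp, "A2"])
            if rel is None:
                mark([snp], "allele_mismatch")
            else:
                relations[key][snp] = rel

    if hla_region is not None:
        chrom, start, end = str(hla_region[0]).removeprefix("chr"), hla_region[1], hla_region[2]
        for df in frames.values():
            in_hla = (df["CHR"].astype(str).str.removeprefix("chr") == chrom) & \
                     (df["BP"] >= start) & (df["BP"] <= end)
            mark(df.loc[in_hla, "SNP"], "hla")

    ids_a = set(frames["a"]["SNP"])
    ids_b = set(frames["b"]["SNP"])
    mark([s for s in all_ids if s not in (ids_a & ids_b)], "not_in_both")

    retained = [s for s in all_ids if s not in removed]
    if not retained:
        raise HarmonizationError("no harmonized SNPs after filtering")

    out = {}
    for key, df in frames.items():
        sub = df[df["SNP"].isin(retained)].copy()
        rel = sub["SNP"].map(relations[key])
        flip_sign = rel.isin(["swap", "flip_swap"]).to_numpy()
        if "BETA" in sub.columns:
            sub.loc[flip_sign, "BETA"] = -sub.loc[flip_sign, "BETA"]
        sub.loc[flip_sign, "Z"] = -sub.loc[flip_sign, "Z"]
        sub["A1"] = sub["SNP"].map(ref["A1"])
        sub["A2"] = sub["SNP"].map(ref["A2"])
        sub = sub.sort_values(["CHR", "BP", "SNP"], kind="mergesort").reset_index(drop=True)
        out[key] = sub

    for snp, reason in removed.items():
        report.n_removed_by_reason[reason] = report.n_removed_by_reason.get(reason, 0) + 1
        report.removed_by_reason.setdefault(reason, []).append(snp)
    report.n_removed_by_reason = {
        r: report.n_removed_by_reason[r] for r in REMOVAL_REASONS
        if r in report.n_removed_by_reason
    }
    report.retained = set(retained)
    report.validate()
    return out["a"], out["b"], report


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Sums the probabilities, conditional on the allele counts, of every
    heterozygote count (same parity) no more probable than the observed
    one.  Monomorphic input returns 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be > 0")
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0

    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (hets * math.log(2.0)
            - gammaln(hom_minor + 1) - gammaln(hom_major + 1) - gammaln(hets + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_genotypes(
    geno: np.ndarray,
    snp_ids: Sequence[str] | None = None,
    controls: Sequence[int] | None = None,
    call_rate: float = 0.95,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-5,
) -> QCReport:
    """QC-filter a 0/1/2 genotype matrix (individuals x SNPs, NaN = missing).

    Individuals with call rate below threshold are removed first; SNP
    filters (call rate, MAF, HWE exact test in controls) are then applied
    in that precedence.  ``controls`` indexes rows used for the HWE test
    (all rows when omitted).
    """
    geno = np.asarray(geno, dtype=float)
    if geno.ndim != 2 or geno.size == 0:
        raise DegenerateInputError("genotype matrix must be non-empty and 2-D")
    n_ind, m = geno.shape
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(m)]
    ind_rate = np.mean(~np.isnan(geno), axis=1)
    keep_ind = ind_rate >= call_rate
    if not keep_ind.any():
        raise DegenerateInputError("all individuals removed by call-rate filter")
    report = QCReport(n_input=m, n_individuals_removed=int((~keep_ind).sum()))
    kept_idx = np.flatnonzero(keep_ind)
    geno = geno[keep_ind]
    if controls is None:
        control_rows = np.arange(geno.shape[0])
    else:
        pos = {orig: new for new, orig in enumerate(kept_idx)}
        control_rows = np.array([pos[c] for c in controls if c in pos], dtype=int)

    for j in range(m):
        col = geno[:, j]
        called = ~np.isnan(col)
        if called.mean() < call_rate:
            reason = "call_rate"
        else:
            freq = np.nanmean(col) / 2.0
            maf = min(freq, 1.0 - freq)
            if maf < maf_min:
                reason = "maf"
            else:
                ctrl = col[control_rows]
                ctrl = ctrl[~np.isnan(ctrl)]
                n_aa = int((ctrl == 2).sum())
                n_Aa = int((ctrl == 1).sum())
                n_AA = int((ctrl == 0).sum())
                if n_AA + n_Aa + n_aa > 0 and hwe_exact_test(n_AA, n_Aa, n_aa) < hwe_p_min:
                    reason = "hwe"
                else:
                    report.retained.add(snp_ids[j])
                    continue
        report.n_removed_by_reason[reason] = report.n_removed_by_reason.get(reason, 0) + 1
        report.removed_by_reason.setdefault(reason, []).append(snp_ids[j])
    report.validate()
    return report


def genomic_inflation(
    chi2: Sequence[float],
    n_cases: int,
    n_controls: int,
    quantile_fraction: float = 0.90,
) -> InflationResult:
    """Median-based inflation factor from the least-significant SNPs.

    lambda = median of the lowest ``quantile_fraction`` of the chi-square
    statistics divided by the chi-square(1) median; lambda_1000 rescales to
    an equivalent study of 1000 cases and 1000 controls.
    """
    chi2 = np.asarray(chi2, dtype=float)
    chi2 = chi2[np.isfinite(chi2)]
    if chi2.size == 0:
        raise ValueError("no finite chi-square values")
    notes = []
    if chi2.size < 100:
        notes.append(f"only {chi2.size} SNPs; inflation estimate unstable")
    k = max(1, int(round(quantile_fraction * chi2.size)))
    subset = np.sort(chi2)[:k]
    lam = float(np.median(subset) / stats.chi2.ppf(0.5, df=1))
    lam_1000 = 1.0 + (lam - 1.0) * (1.0 / n_cases + 1.0 / n_controls) / (2.0 / 1000.0)
    return InflationResult(lambda_gc=lam, lambda_1000=lam_1000,
                           n_snps_used=k, warnings=notes)
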