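"""GWAS summary-statistics I/O, filtering and allele harmonization.

Summary statistics are per-variant marginal regression effects (beta, SE,
p, N, effect-allele frequency). Before posterior-mean re-weighting they are
restricted to a well-behaved variant set (HapMap3-style), purged of the MHC
region on chromosome 6, aligned to a reference panel's allele orientation
(strand flips, allele swaps, ambiguous A/T-C/G handling) and converted to
the standardized scale z/sqrt(n) used by the weight engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStats",
    "HarmonizationReport",
    "GIANT_DIALECT",
    "DEFAULT_HLA_REGION",
    "read_sumstats",
    "write_sumstats",
    "restrict_to_panel",
    "exclude_region",
    "harmonize_alleles",
    "standardize_effects",
]

_CANONICAL = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "eaf", "beta", "se", "p", "n"]
_MANDATORY = ["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "p", "n"]

#: GIANT-style column map (canonical field -> file column).
GIANT_DIALECT = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "Freq",
    "beta": "b",
    "se": "se",
    "p": "p",
    "n": "N",
}

#: Extended-MHC exclusion interval (chrom, start, end), 1-based inclusive.
DEFAULT_HLA_REGION = ("6", 25_000_000, 34_000_000)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SummaryStats:
    """Per-variant marginal GWAS effects with alleles, frequency and N.

    Backed by a DataFrame with columns ``variant_id, chrom, pos,
    effect_allele, other_allele, eaf, beta, se, p, n`` (chrom/pos may be
    missing) plus an optional ``flag`` column marking rows (e.g.
    ``monomorphic``) that carry no usable effect but are retained for
    accounting.
    """

    df: pd.DataFrame
    read_report: Optional[dict] = None

    def __post_init__(self):
        missing = [c for c in _MANDATORY if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        for c in ("chrom", "pos", "flag"):
            if c not in self.df.columns:
                self.df[c] = "" if c != "pos" else np.nan
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> pd.Series:
        return self.df["variant_id"]

    def usable(self) -> "SummaryStats":
        """Rows with a defined effect (unflagged)."""
        mask = (self.df["flag"].fillna("") == "") & self.df["beta"].notna()
        return SummaryStats(self.df.loc[mask].reset_index(drop=True))

    def validate(self) -> None:
        d = self.usable().df
        if d["variant_id"].duplicated().any():
            raise ValueError("duplicate variant_id")
        if (d["effect_allele"] == d["other_allele"]).any():
            raise ValueError("effect_allele equals other_allele")
        if (d["se"] <= 0).any():
            raise ValueError("se must be positive")
        if ((d["eaf"] <= 0) | (d["eaf"] >= 1)).any():
            raise ValueError("eaf must be in (0, 1)")
        if ((d["p"] <= 0) | (d["p"] > 1)).any():
            raise ValueError("p must be in (0, 1]")
        if (d["n"] < 1).any():
            raise ValueError("n must be >= 1")


@dataclass
class HarmonizationReport:
    """Disjoint per-variant outcome counts; they sum to the input size."""

    kept: int = 0
    strand_flipped: int = 0
    allele_swapped: int = 0
    ambiguous_dropped: int = 0
    unmatched_dropped: int = 0
    duplicate_dropped: int = 0

    @property
    def total(self) -> int:
        return (
            self.kept
            + self.strand_flipped
            + self.allele_swapped
            + self.ambiguous_dropped
            + self.unmatched_dropped
            + self.duplicate_dropped
        )

    @property
    def n_retained(self) -> int:
        return self.kept + self.strand_flipped + self.allele_swapped


def read_sumstats(path, dialect: Optional[dict] = None) -> SummaryStats:
    """Read a TSV of GWAS summary statistics.

    ``dialect`` maps canonical field names to file column names (default:
    GIANT-style ``SNP, A1, A2, Freq, b, se, p, N`` with optional CHR/POS).
    Malformed rows (non-ACGT alleles, se <= 0, frequency or p out of range,
    n < 1, duplicate ids) are dropped and counted in ``read_report``; a
    missing mandatory column is a hard error naming it.
    """
    dialect = dict(GIANT_DIALECT if dialect is None else dialect)
    raw = pd.read_csv(path, sep="\t", dtype={dialect.get("chrom", "CHR"): str})
    for canon in _MANDATORY:
        col = dialect.get(canon, canon)
        if col not in raw.columns:
            raise ValueError(f"mandatory column '{col}' (field '{canon}') missing from {path}")
    df = pd.DataFrame()
    for canon in _CANONICAL:
        col = dialect.get(canon, canon)
        if col in raw.columns:
            df[canon] = raw[col]
    n_in = len(df)
    report = {"n_input": n_in}
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for c in ("eaf", "beta", "se", "p", "n"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    bad_allele = ~(
        df["effect_allele"].isin(list("ACGT"))
        & df["other_allele"].isin(list("ACGT"))
        & (df["effect_allele"] != df["other_allele"])
    )
    bad_num = (
        df[["eaf", "beta", "se", "p", "n"]].isna().any(axis=1)
        | (df["se"] <= 0)
        | (df["eaf"] <= 0)
        | (df["eaf"] >= 1)
        | (df["p"] <= 0)
        | (df["p"] > 1)
        | (df["n"] < 1)
    )
    dup = df["variant_id"].duplicated()
    report["dropped_bad_allele"] = int((bad_allele & ~bad_num).sum())
    report["dropped_malformed"] = int(bad_num.sum())
    report["dropped_duplicate"] = int((dup & ~bad_allele & ~bad_num).sum())
    keep = ~(bad_allele | bad_num | dup)
    report["n_kept"] = int(keep.sum())
    if report["n_kept"] < n_in:
        warnings.warn(
            f"read_sumstats: dropped {n_in - report['n_kept']} of {n_in} rows "
            f"({report})",
            stacklevel=2,
        )
    out = SummaryStats(df.loc[keep].reset_index(drop=True), read_report=report)
    out.validate()
    return out


def write_sumstats(stats: SummaryStats, path, dialect: Optional[dict] = None) -> None:
    """Write summary statistics as TSV using ``dialect`` column names."""
    dialect = dict(GIANT_DIALECT if dialect is None else dialect)
    cols = {dialect.get(c, c): stats.df[c] for c in _CANONICAL if c in stats.df.columns}
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def restrict_to_panel(stats: SummaryStats, keep_ids: Iterable[str]) -> SummaryStats:
    """Keep only variants whose id is in ``keep_ids`` (HapMap3-style filter)."""
    keep_ids = set(keep_ids)
    if not keep_ids:
        raise ValueError("keep_ids is empty")
    mask = stats.df["variant_id"].isin(keep_ids)
    if not mask.any():
        raise ValueError("no summary-statistics variants intersect the panel: nothing to train on")
    return SummaryStats(stats.df.loc[mask].reset_index(drop=True))


def exclude_region(stats: SummaryStats, chrom: str, start: int, end: int) -> SummaryStats:
    """Drop variants inside a 1-based inclusive interval (e.g. the MHC)."""
    if start > end:
        raise ValueError("start must not exceed end")
    chrom = str(chrom).removeprefix("chr")
    c = stats.df["chrom"].astype(str).str.removeprefix("chr")
    pos = pd.to_numeric(stats.df["pos"], errors="coerce")
    inside = (c == chrom) & (pos >= start) & (pos <= end)
    return SummaryStats(stats.df.loc[~inside].reset_index(drop=True))


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(_COMPLEMENT)


def harmonize_alleles(
    stats: SummaryStats,
    ref_meta: pd.DataFrame,
    *,
    ambiguity_maf: float = 0.40,
    ref_freq: Optional[np.ndarray] = None,
):
    """Align effect alleles to a reference panel's counted allele.

    ``ref_meta`` needs columns ``variant_id, allele_a, allele_b``; the
    counted (dosage) allele is ``allele_b``. Cases per variant:

    * exact orientation match — kept as-is;
    * swapped alleles — beta negated, eaf complemented;
    * strand-complement match — alleles flipped, beta unchanged (a
      flip+swap combination is counted under ``allele_swapped``);
    * ambiguous pair (A/T or C/G): dropped when min(eaf, 1-eaf) exceeds
      ``ambiguity_maf``, else resolved by frequency agreement against
      ``ref_freq`` (frequency of allele_b in the reference) when supplied,
      by literal letter match otherwise;
    * no orientation matches — dropped as unmatched.

    Returns ``(SummaryStats, HarmonizationReport)``; the report's counts
    partition the input variants.
    """
    rep = HarmonizationReport()
    df = stats.df.copy()
    dup = df["variant_id"].duplicated()
    rep.duplicate_dropped = int(dup.sum())
    df = df.loc[~dup]

    ref = ref_meta.drop_duplicates("variant_id", keep="first")
    ref_cols = ref[["variant_id", "allele_a", "allele_b"]].copy()
    if ref_freq is not None:
        ref_cols["ref_freq"] = np.asarray(ref_freq)[~ref_meta["variant_id"].duplicated().to_numpy()]
    merged = df.merge(ref_cols, on="variant_id", how="left", suffixes=("", "_ref"))

    matched = merged["allele_b"].notna()
    e, o = merged["effect_allele"], merged["other_allele"]
    a, b = merged["allele_a"], merged["allele_b"]
    ce, co = _complement(e), _complement(o)

    ambiguous = matched & (o == ce)
    exact = matched & (e == b) & (o == a)
    swap = matched & (e == a) & (o == b)
    flip = matched & (ce == b) & (co == a)
    flipswap = matched & (ce == a) & (co == b)

    # Resolution order for unambiguous pairs: exact > swap > flip > flip+swap.
    case = np.full(len(merged), "unmatched", dtype=object)
    case[(flipswap & ~ambiguous).to_numpy()] = "flipswap"
    case[(flip & ~ambiguous).to_numpy()] = "flip"
    case[(swap & ~ambiguous).to_numpy()] = "swap"
    case[(exact & ~ambiguous).to_numpy()] = "exact"

    # Ambiguous pairs: orientation is unidentifiable from letters alone.
    amb = ambiguous & (exact | swap | flip | flipswap)
    maf = np.minimum(merged["eaf"], 1 - merged["eaf"])
    amb_drop = amb & (maf > ambiguity_maf)
    amb_keep = amb & ~amb_drop
    case[amb_drop.to_numpy()] = "ambiguous"
    if amb_keep.any():
        if "ref_freq" in merged.columns and merged.loc[amb_keep, "ref_freq"].notna().all():
            # Keep orientation whose implied frequency is nearer the panel's.
            fr = merged.loc[amb_keep, "ref_freq"]
            same = (merged.loc[amb_keep, "eaf"] - fr).abs() <= ((1 - merged.loc[amb_keep, "eaf"]) - fr).abs()
            eq_letters = merged.loc[amb_keep, "effect_allele"] == merged.loc[amb_keep, "allele_b"]
            case[amb_keep.to_numpy()] = np.where(
                same, np.where(eq_letters, "exact", "flip"), np.where(eq_letters, "flipswap", "swap")
            )
        else:
            eq_letters = merged.loc[amb_keep, "effect_allele"] == merged.loc[amb_keep, "allele_b"]
            case[amb_keep.to_numpy()] = np.where(eq_letters, "exact", "swap")

    case = pd.Series(case, index=merged.index)
    negate = case.isin(["swap", "flipswap"])
    keepers = case.isin(["exact", "swap", "flip", "flipswap"])

    rep.kept = int((case == "exact").sum())
    rep.strand_flipped = int((case == "flip").sum())
    rep.allele_swapped = int(negate.sum())
    rep.ambiguous_dropped = int((case == "ambiguous").sum())
    rep.unmatched_dropped = int((case == "unmatched").sum())

    out = merged.loc[keepers].copy()
    out.loc[negate[keepers], "beta"] = -out.loc[negate[keepers], "beta"]
    out.loc[negate[keepers], "eaf"] = 1.0 - out.loc[negate[keepers], "eaf"]
    out["effect_allele"] = out["allele_b"]
    out["other_allele"] = out["allele_a"]
    out = out[[c for c in stats.df.columns if c in out.columns]].reset_index(drop=True)
    assert rep.total == len(stats.df)
    return SummaryStats(out), rep


def standardize_effects(stats: SummaryStats) -> np.ndarray:
    """Standardized marginal effects z/sqrt(n), z = beta/se.

    These live on the scale of the correlation between standardized genotype
    and standardized phenotype; the weight engine operates on this scale and
    back-converts to per-allele units at the end. A >50% spread in per-variant
    N (meta-analysis heterogeneity) triggers a warning, not an error.
    """
    d = stats.usable().df
    n = d["n"].to_numpy(dtype=float)
    if len(n) and n.max() > 1.5 * n.min():
        warnings.warn("per-variant sample size varies by more than 50%", stacklevel=2)
    z = d["beta"].to_numpy() / d["se"].to_numpy()
    return z / np.sqrt(n)
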