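"""Per-individual polygenic score computation: PRS_i = sum_j w_j g_ij.

The per-site step of the federated protocol: a site receives a weight file,
aligns weight alleles to its own genotype panel (same flip/swap logic as
summary-statistics harmonization) and computes dosage-weighted sums. Missing
dosages are mean-imputed with the cohort allele frequency, which shifts all
scores by a constant and leaves ranks unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Tuple

import numpy as np
import pandas as pd

from transprs.ldpred_core import WeightSet
from transprs.sumstats import HarmonizationReport, SummaryStats, harmonize_alleles
from transprs.synthetic_data import GenotypePanel

__all__ = ["ScoreTable", "align_weights", "compute_prs", "score_panel"]


@dataclass
class ScoreTable:
    """PRS values per individual, one column per weight set.

    ``df`` holds ``sample_id`` plus one score column named
    ``"<ld_panel>:<fraction>"``; ``n_variants_used`` maps each column to the
    number of weights actually applied.
    """

    df: pd.DataFrame
    n_variants_used: Dict[str, int]

    def scores(self, column: str) -> np.ndarray:
        return self.df[column].to_numpy()

    @property
    def score_columns(self) -> list:
        return [c for c in self.df.columns if c != "sample_id"]

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "ScoreTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df, {c: -1 for c in df.columns if c != "sample_id"})


def align_weights(
    panel: GenotypePanel,
    weights: WeightSet,
    *,
    ambiguity_maf: float = 0.40,
) -> Tuple[np.ndarray, HarmonizationReport]:
    """Orient a weight set to a genotype panel's counted alleles.

    Reuses the summary-statistics harmonization engine with the weight as the
    'effect': exact matches keep their sign, swapped or flip+swapped alleles
    negate the weight, strand flips keep it, unmatched and high-MAF
    ambiguous weights are dropped and counted. Returns a weight vector
    aligned to the panel's variant order (zero where no weight applies) and
    the usage report. Fewer than 50% matched weights is a hard error.
    """
    wdf = weights.df
    proxy = pd.DataFrame(
        {
            "variant_id": wdf["variant_id"],
            "effect_allele": wdf["effect_allele"],
            "other_allele": wdf["other_allele"],
            "eaf": wdf["freq"] if "freq" in wdf.columns else 0.5,
            "beta": wdf["weight"],
            "se": 1.0,
            "p": 1.0,
            "n": 1,
        }
    )
    panel_freq = panel.allele_frequencies()
    harmonized, rep = harmonize_alleles(
        SummaryStats(proxy),
        panel.variant_meta,
        ambiguity_maf=ambiguity_maf,
        ref_freq=panel_freq,
    )
    if rep.n_retained < 0.5 * len(wdf):
        raise ValueError(
            f"only {rep.n_retained}/{len(wdf)} weights matched the panel; "
            "cohort/weight-set mismatch"
        )
    w = np.zeros(panel.n_variants)
    pos = pd.Index(panel.variant_meta["variant_id"]).get_indexer(harmonized.df["variant_id"])
    w[pos] = harmonized.df["beta"].to_numpy()
    return w, rep


def compute_prs(panel: GenotypePanel, aligned_weights: np.ndarray) -> Tuple[np.ndarray, int]:
    """Weighted dosage sum per individual.

    Missing dosages are replaced by 2f with f the cohort allele frequency;
    fully missing variants are excluded (their weight zeroed) and counted.
    Returns (scores, n_variants_used).
    """
    w = np.asarray(aligned_weights, dtype=float)
    if w.shape[0] != panel.n_variants:
        raise ValueError("weight vector length does not match panel")
    x = panel.dosages.astype(np.float64, copy=False)
    nan_mask = np.isnan(x)
    used = w != 0.0
    if nan_mask.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_mean = np.nanmean(x, axis=0)
        all_missing = np.isnan(col_mean)
        if (all_missing & used).any():
            warnings.warn(
                f"{int((all_missing & used).sum())} weighted variants are fully missing; excluded",
                stacklevel=2,
            )
            w = np.where(all_missing, 0.0, w)
            used = w != 0.0
        x = np.where(nan_mask, np.where(np.isnan(col_mean), 0.0, col_mean), x)
    return x @ w, int(used.sum())


def score_panel(
    panel: GenotypePanel,
    weight_sets: Iterable[WeightSet],
    *,
    ambiguity_maf: float = 0.40,
    standardize: bool = False,
) -> ScoreTable:
    """Score a cohort with every weight set; one column per (panel, fraction)."""
    df = pd.DataFrame({"sample_id": panel.sample_meta["sample_id"].to_numpy()})
    used: Dict[str, int] = {}
    for ws in weight_sets:
        col = f"{ws.ld_panel}:{ws.fraction_label}"
        aligned, _ = align_weights(panel, ws, ambiguity_maf=ambiguity_maf)
        scores, n_used = compute_prs(panel, aligned)
        if standardize:
            sd = scores.std()
            scores = (scores - scores.mean()) / (sd if sd > 0 else 1.0)
        df[col] = scores
        used[col] = n_used
    return ScoreTable(df, used)
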