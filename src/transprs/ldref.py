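"""LD reference panels: ancestry assignment, selection, pooling, windowed LD.

A reference panel exists only to estimate local genotype correlation (LD).
Population-specific panels capture one ancestry's LD; a pooled
"trans-ethnic" panel concatenates all of them, which attenuates
population-private LD and is the mechanism that lets European-trained
weights port across ancestries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from transprs.synthetic_data import GenotypePanel

__all__ = [
    "LDReference",
    "assign_ancestry_pca",
    "select_ld_panel",
    "pool_trans_ethnic",
    "compute_ld_windows",
    "default_window_size",
]


@dataclass
class LDReference:
    """Windowed SNP-SNP correlation matrices from one reference panel.

    ``windows`` are half-open variant-index ranges partitioning the variant
    list; ``matrices[i]`` is the shrunk Pearson correlation matrix of window
    i: (1 - lambda) * R + lambda * I, symmetric PSD with unit diagonal.
    ``freqs`` is the panel frequency of allele_b, used for per-allele
    back-conversion of standardized weights.
    """

    windows: List[Tuple[int, int]]
    matrices: List[np.ndarray]
    variant_meta: pd.DataFrame
    freqs: np.ndarray
    source_populations: List[Tuple[str, int]]
    shrinkage_lambda: float
    label: str = "panel"

    @property
    def n_variants(self) -> int:
        return len(self.variant_meta)

    def validate(self) -> None:
        covered = []
        for (a, b), mat in zip(self.windows, self.matrices):
            covered.extend(range(a, b))
            if mat.shape != (b - a, b - a):
                raise ValueError("window/matrix shape mismatch")
            if not np.allclose(mat, mat.T, atol=1e-8):
                raise ValueError("LD matrix not symmetric")
            if not np.allclose(np.diag(mat), 1.0, atol=1e-8):
                raise ValueError("LD matrix diagonal not 1")
            if np.linalg.eigvalsh(mat).min() < -1e-8:
                raise ValueError("LD matrix not PSD after shrinkage")
        if covered != list(range(self.n_variants)):
            raise ValueError("windows do not partition the variant list")

    def subset_variants(self, idx) -> "LDReference":
        """Restrict to a sorted subset of variant indices, re-windowing.

        Correlations between retained variants are kept as estimated; the
        window partition is rebuilt over the survivors.
        """
        idx = np.asarray(idx)
        if len(idx) and (np.diff(idx) <= 0).any():
            raise ValueError("variant subset indices must be strictly increasing")
        windows, matrices = [], []
        offset = 0
        for (a, b), mat in zip(self.windows, self.matrices):
            local = idx[(idx >= a) & (idx < b)] - a
            if local.size == 0:
                continue
            windows.append((offset, offset + local.size))
            matrices.append(np.ascontiguousarray(mat[np.ix_(local, local)]))
            offset += local.size
        return LDReference(
            windows=windows,
            matrices=matrices,
            variant_meta=self.variant_meta.iloc[idx].reset_index(drop=True),
            freqs=self.freqs[idx],
            source_populations=self.source_populations,
            shrinkage_lambda=self.shrinkage_lambda,
            label=self.label,
        )

    def save(self, path) -> None:
        header = {
            "label": self.label,
            "shrinkage_lambda": self.shrinkage_lambda,
            "source_populations": [[lab, int(n)] for lab, n in self.source_populations],
            "windows": [[int(a), int(b)] for a, b in self.windows],
            "variant_meta_columns": list(self.variant_meta.columns),
        }
        arrays = {f"window_{i}": m for i, m in enumerate(self.matrices)}
        arrays["freqs"] = self.freqs
        for c in self.variant_meta.columns:
            col = self.variant_meta[c].to_numpy()
            arrays[f"meta_{c}"] = col.astype(str) if col.dtype == object else col
        np.savez_compressed(path, header=json.dumps(header), **arrays)

    @classmethod
    def load(cls, path) -> "LDReference":
        with np.load(path, allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            windows = [tuple(w) for w in header["windows"]]
            matrices = [z[f"window_{i}"] for i in range(len(windows))]
            meta = pd.DataFrame(
                {c: z[f"meta_{c}"] for c in header["variant_meta_columns"]}
            )
            for c in ("variant_id", "chrom", "allele_a", "allele_b"):
                if c in meta.columns:
                    meta[c] = meta[c].astype(str)
            return cls(
                windows=windows,
                matrices=matrices,
                variant_meta=meta,
                freqs=z["freqs"],
                source_populations=[(lab, int(n)) for lab, n in header["source_populations"]],
                shrinkage_lambda=header["shrinkage_lambda"],
                label=header["label"],
            )


def _patterson_standardize(dosages: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Center by 2f and scale by sqrt(2f(1-f)); monomorphic columns -> 0."""
    f = np.clip(freqs, 0.0, 1.0)
    denom = np.sqrt(2.0 * f * (1.0 - f))
    denom[denom == 0] = 1.0
    z = (dosages - 2.0 * f) / denom
    return np.nan_to_num(z, nan=0.0)


def assign_ancestry_pca(
    panel: GenotypePanel,
    reference: GenotypePanel,
    k: int = 2,
) -> pd.DataFrame:
    """Project a cohort onto reference PCs and label by nearest centroid.

    Loadings come from the reference only (Patterson standardization using
    reference frequencies); target individuals are projected onto those
    axes and assigned the label of the nearest reference-population centroid
    in k-dimensional PC space. Returns a DataFrame with sample_id, the
    assigned ``population`` label, the centroid ``distance`` and PC columns.
    """
    ref_ids = reference.variant_meta["variant_id"]
    common = panel.variant_meta["variant_id"].isin(set(ref_ids))
    if int(common.sum()) < 50:
        raise ValueError("fewer than 50 overlapping variants between panel and reference")
    idx_panel = np.flatnonzero(common.to_numpy())
    order = pd.Index(ref_ids).get_indexer(panel.variant_meta["variant_id"].iloc[idx_panel])
    labels = reference.sample_meta["population"]
    if labels.nunique() < 2:
        raise ValueError("reference must contain at least 2 labelled populations")

    ref_x = reference.dosages[:, order].astype(np.float64)
    f = np.nanmean(ref_x, axis=0) / 2.0
    z_ref = _patterson_standardize(ref_x, f)
    z_ref -= z_ref.mean(axis=0)
    u, s, vt = np.linalg.svd(z_ref, full_matrices=False)
    if np.sum(s > 1e-8 * s[0]) < k:
        raise ValueError(f"reference supports fewer than {k} non-degenerate PCs")
    pcs_ref = u[:, :k] * s[:k]
    z_tgt = _patterson_standardize(panel.dosages[:, idx_panel].astype(np.float64), f)
    pcs_tgt = z_tgt @ vt[:k].T

    centroids = {lab: pcs_ref[(labels == lab).to_numpy()].mean(axis=0) for lab in labels.unique()}
    labs = list(centroids)
    cent = np.stack([centroids[lab] for lab in labs])
    dist = np.linalg.norm(pcs_tgt[:, None, :] - cent[None, :, :], axis=2)
    nearest = dist.argmin(axis=1)
    out = pd.DataFrame(
        {
            "sample_id": panel.sample_meta["sample_id"].to_numpy(),
            "population": [labs[i] for i in nearest],
            "distance": dist[np.arange(len(nearest)), nearest],
        }
    )
    for j in range(k):
        out[f"PC{j + 1}"] = pcs_tgt[:, j]
    out.attrs["centroids"] = {lab: centroids[lab] for lab in labs}
    return out


def select_ld_panel(
    panel: GenotypePanel,
    population: str,
    max_n: int,
    *,
    seed: int = 0,
    labels: Optional[pd.Series] = None,
) -> GenotypePanel:
    """Select up to ``max_n`` individuals carrying a population label.

    ``labels`` overrides ``panel.sample_meta['population']`` (e.g. output of
    :func:`assign_ancestry_pca`). When more individuals are available than
    ``max_n``, a uniform subsample is drawn deterministically under ``seed``.
    """
    lab = panel.sample_meta["population"] if labels is None else pd.Series(np.asarray(labels))
    idx = np.flatnonzero((lab == population).to_numpy())
    if idx.size == 0:
        raise ValueError(f"no individuals labelled '{population}' available")
    if idx.size > max_n:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
        idx = np.sort(rng.choice(idx, size=max_n, replace=False))
    else:
        if idx.size < max_n:
            warnings.warn(
                f"only {idx.size} individuals labelled '{population}' (requested {max_n})",
                stacklevel=2,
            )
    sub = panel.subset_samples(idx)
    sub.label = population
    return sub


def pool_trans_ethnic(panels: Sequence[GenotypePanel]) -> GenotypePanel:
    """Concatenate reference panels into one pooled (trans-ethnic) panel.

    Panels must agree on the variant list and allele orientation; panels
    with differing variant sets are intersected and aligned by variant_id,
    reporting the loss. An allele-convention mismatch on shared variants is
    a hard error — harmonize first.
    """
    if not panels:
        raise ValueError("no panels to pool")
    base = panels[0]
    ids0 = base.variant_meta["variant_id"]
    common = set(ids0)
    for p in panels[1:]:
        common &= set(p.variant_meta["variant_id"])
    if not common:
        raise ValueError("panels share no variants")
    keep_ids = [v for v in ids0 if v in common]
    aligned = []
    for p in panels:
        pos = pd.Index(p.variant_meta["variant_id"]).get_indexer(keep_ids)
        sub = p.subset_variants(pos)
        aligned.append(sub)
        if len(keep_ids) < p.n_variants:
            warnings.warn(
                f"pool_trans_ethnic: dropped {p.n_variants - len(keep_ids)} variants "
                f"not shared across panels",
                stacklevel=2,
            )
    vm0 = aligned[0].variant_meta
    for sub in aligned[1:]:
        if not (
            (sub.variant_meta["allele_a"].to_numpy() == vm0["allele_a"].to_numpy()).all()
            and (sub.variant_meta["allele_b"].to_numpy() == vm0["allele_b"].to_numpy()).all()
        ):
            raise ValueError("allele convention differs between panels; harmonize before pooling")
    dosages = np.vstack([s.dosages for s in aligned])
    sample_meta = pd.concat([s.sample_meta for s in aligned], ignore_index=True)
    # keep only columns common to all panels (admixture columns may differ)
    pooled = GenotypePanel(
        dosages=dosages,
        variant_meta=vm0.reset_index(drop=True),
        sample_meta=sample_meta,
        label="TE",
    )
    return pooled


def default_window_size(n_variants: int) -> int:
    """Conventional LD radius M/3000 SNPs, floored at 50 SNPs per window."""
    return max(50, 2 * int(round(n_variants / 3000)))


def compute_ld_windows(
    panel: GenotypePanel,
    window_size: Optional[int] = None,
    shrinkage_lambda: float = 0.01,
    label: Optional[str] = None,
) -> LDReference:
    """Windowed Pearson-correlation LD with ridge shrinkage.

    Dosages are mean-imputed per variant, variants are split into
    consecutive windows of ``window_size`` SNPs (a locality approximation:
    LD is treated as zero across window boundaries), and each window's
    correlation matrix is regularized as (1 - lambda) R + lambda I, which
    keeps the matrices PSD for downstream solves and sampling. Monomorphic
    variants get zero off-diagonal correlation and are flagged.
    """
    if not (0.0 <= shrinkage_lambda <= 1.0):
        raise ValueError("shrinkage_lambda must be in [0, 1]")
    m = panel.n_variants
    if window_size is None:
        window_size = default_window_size(m)
    x = panel.dosages.astype(np.float64)
    mono_flags = []
    col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    nan_mask = np.isnan(x)
    if nan_mask.any():
        x[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    mono = sd == 0
    mono_flags = np.flatnonzero(mono)
    sd_safe = np.where(mono, 1.0, sd)
    z = x / sd_safe
    n = panel.n_samples
    windows, matrices = [], []
    for start in range(0, m, window_size):
        stop = min(start + window_size, m)
        zw = z[:, start:stop]
        r = (zw.T @ zw) / n
        mono_w = mono[start:stop]
        if mono_w.any():
            r[mono_w, :] = 0.0
            r[:, mono_w] = 0.0
        np.fill_diagonal(r, 1.0)
        r = (1.0 - shrinkage_lambda) * r + shrinkage_lambda * np.eye(stop - start)
        r = (r + r.T) / 2.0
        windows.append((start, stop))
        matrices.append(r)
    if len(mono_flags):
        warnings.warn(
            f"compute_ld_windows: {len(mono_flags)} monomorphic variants zeroed in LD",
            stacklevel=2,
        )
    pops = (
        panel.sample_meta["population"].value_counts().items()
        if "population" in panel.sample_meta.columns
        else [(panel.label or "panel", n)]
    )
    ld = LDReference(
        windows=windows,
        matrices=matrices,
        variant_meta=panel.variant_meta.reset_index(drop=True),
        freqs=col_mean / 2.0,
        source_populations=[(str(lab), int(cnt)) for lab, cnt in pops],
        shrinkage_lambda=shrinkage_lambda,
        label=label or panel.label or "panel",
    )
    return ld
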