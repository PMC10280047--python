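"""Multi-population genotype, phenotype and GWAS simulator.

Emulates the statistical structure a cross-ancestry PRS pipeline assumes:

* population allele-frequency divergence under the Balding-Nichols model
  (Beta-distributed frequencies around a shared ancestral pool, indexed by
  F_ST);
* local linkage disequilibrium via blockwise order-1 autoregressive latent
  Gaussian haplotypes thresholded at the allele-frequency quantile;
* admixed cohorts with Dirichlet-distributed individual ancestry and
  block-level ancestry assignment (preserving within-block founder LD);
* additive polygenic phenotypes with a configurable causal fraction and
  narrow-sense heritability on the standardized scale;
* marginal per-SNP GWAS summary statistics from simple linear regression.

Dosages count copies of ``allele_b`` (the effect allele throughout the
package).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

__all__ = [
    "SimulationConfig",
    "GenotypePanel",
    "TraitModel",
    "balding_nichols",
    "variant_table",
    "simulate_frequencies",
    "simulate_genotypes",
    "simulate_admixed",
    "simulate_phenotype",
    "simulate_gwas",
]

_BASES = np.array(list("ACGT"))


def _rng(seed_parts) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed_parts))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic multi-population experiment.

    Defaults are the desk-scale analogue of the real study: M = 2000 variants
    in 40 LD blocks, three founder populations at pairwise F_ST 0.12, a
    training GWAS of N = 20 000, a polygenic trait with 3% causal variants
    and h^2 = 0.25.
    """

    n_variants: int = 2000
    n_blocks: int = 40
    block_rho: float = 0.6
    fst_matrix: object = 0.12  # scalar (all pairs) or (k, k) pairwise matrix
    populations: tuple = (("EUR", 2500), ("ASN", 2500), ("AFR", 2500))
    admixture_alpha: tuple = (1.0, 1.0, 1.0)
    p_causal: float = 0.03
    h2: float = 0.25
    n_gwas: int = 20000
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.n_blocks <= self.n_variants):
            raise ValueError("need n_variants >= n_blocks >= 1")
        if not (0.0 <= self.block_rho < 1.0):
            raise ValueError("block_rho must be in [0, 1)")
        if not (0.0 < self.p_causal <= 1.0):
            raise ValueError("p_causal must be in (0, 1]")
        if not (0.0 <= self.h2 < 1.0):
            raise ValueError("h2 must be in [0, 1)")
        fst = np.atleast_2d(np.asarray(self.fst_matrix, dtype=float))
        if np.any(fst < 0.0) or np.any(fst >= 1.0):
            raise ValueError("all F_ST values must be in [0, 1)")

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def population_labels(self) -> list:
        return [lab for lab, _ in self.populations]

    def pairwise_fst(self) -> np.ndarray:
        """Pairwise F_ST matrix (scalar input broadcast to all pairs)."""
        k = self.n_populations
        f = np.asarray(self.fst_matrix, dtype=float)
        if f.ndim == 0:
            m = np.full((k, k), float(f))
            np.fill_diagonal(m, 0.0)
            return m
        if f.shape != (k, k):
            raise ValueError(f"fst_matrix must be scalar or ({k}, {k})")
        return f

    def per_population_fst(self) -> np.ndarray:
        """Per-population divergence F_i from the shared ancestral pool.

        Under Balding-Nichols drift from a common ancestor, pairwise
        differentiation is approximately additive: F_ij ~ F_i + F_j for
        modest F. The per-population values are the least-squares solution
        of that system given the configured pairwise matrix.
        """
        k = self.n_populations
        if k == 1:
            f = self.pairwise_fst()
            return np.zeros(1)
        m = self.pairwise_fst()
        rows, rhs = [], []
        for i in range(k):
            for j in range(i + 1, k):
                r = np.zeros(k)
                r[i] = r[j] = 1.0
                rows.append(r)
                rhs.append(m[i, j])
        sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
        return np.clip(sol, 0.0, 1.0 - 1e-9)

    def block_bounds(self) -> list:
        """Half-open [start, stop) variant-index ranges of the LD blocks."""
        edges = np.linspace(0, self.n_variants, self.n_blocks + 1).round().astype(int)
        return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:]) if b > a]


@dataclass
class TraitModel:
    """Shared causal architecture applied across cohorts of one experiment."""

    causal_idx: np.ndarray  # indices of causal variants
    effects_per_allele: np.ndarray  # length M, zero off the causal set
    env_sd: float  # residual (environmental) standard deviation


@dataclass
class GenotypePanel:
    """Dosage matrix (individuals x variants) with variant/sample metadata.

    ``dosages`` holds copies of ``allele_b`` in [0, 2]; NaN marks missing.
    ``variant_meta`` columns: variant_id, chrom, pos, allele_a, allele_b.
    ``sample_meta`` columns: sample_id, population (plus optional
    ``anc_<label>`` admixture-proportion columns).
    """

    dosages: np.ndarray
    variant_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    phenotype: Optional[np.ndarray] = None
    label: Optional[str] = None

    def __post_init__(self):
        n, m = self.dosages.shape
        if len(self.variant_meta) != m:
            raise ValueError("variant_meta length does not match dosage columns")
        if len(self.sample_meta) != n:
            raise ValueError("sample_meta length does not match dosage rows")
        if self.phenotype is not None and len(self.phenotype) != n:
            raise ValueError("phenotype length does not match dosage rows")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed frequency of allele_b per variant (missing-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def validate(self) -> None:
        d = self.dosages
        ok = np.isnan(d) | ((d >= 0) & (d <= 2))
        if not np.all(ok):
            raise ValueError("dosages must be in [0, 2] or NaN")
        vm = self.variant_meta
        for c in ("allele_a", "allele_b"):
            if not vm[c].isin(list("ACGT")).all():
                raise ValueError("alleles must be in {A,C,G,T}")
        for _, grp in vm.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing within chromosome")

    def subset_samples(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            dosages=self.dosages[idx],
            variant_meta=self.variant_meta,
            sample_meta=self.sample_meta.iloc[idx].reset_index(drop=True),
            phenotype=None if self.phenotype is None else self.phenotype[idx],
            label=self.label,
        )

    def subset_variants(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            dosages=self.dosages[:, idx],
            variant_meta=self.variant_meta.iloc[idx].reset_index(drop=True),
            sample_meta=self.sample_meta,
            phenotype=self.phenotype,
            label=self.label,
        )


def balding_nichols(p0: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Draw descendant-population allele frequencies around ancestral ``p0``.

    Frequencies follow Beta(p0*(1-F)/F, (1-p0)*(1-F)/F), whose mean is p0
    and variance F*p0*(1-p0). F = 0 short-circuits to p0 exactly (the Beta
    parameters diverge in that limit).
    """
    p0 = np.asarray(p0, dtype=float)
    if not (0.0 <= fst < 1.0):
        raise ValueError("fst must be in [0, 1)")
    if fst == 0.0:
        return p0.copy()
    scale = (1.0 - fst) / fst
    draws = rng.beta(p0 * scale, (1.0 - p0) * scale)
    return np.clip(draws, 1e-6, 1.0 - 1e-6)


def variant_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic variant metadata (ids, positions, random allele pairs)."""
    rng = _rng([config.seed, 101])
    m = config.n_variants
    a_idx = rng.integers(0, 4, size=m)
    shift = rng.integers(1, 4, size=m)
    b_idx = (a_idx + shift) % 4
    width = max(6, len(str(m)))
    return pd.DataFrame(
        {
            "variant_id": [f"snp{i:0{width}d}" for i in range(1, m + 1)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 5000,
            "allele_a": _BASES[a_idx],
            "allele_b": _BASES[b_idx],
        }
    )


def simulate_frequencies(config: SimulationConfig) -> np.ndarray:
    """Per-population allele-frequency matrix (populations x variants).

    Ancestral frequencies are Uniform(0.05, 0.95); each population diverges
    by its Balding-Nichols F (derived from the configured pairwise F_ST).
    """
    rng = _rng([config.seed, 102])
    p0 = rng.uniform(0.05, 0.95, size=config.n_variants)
    per_pop = config.per_population_fst()
    return np.stack([balding_nichols(p0, float(f), rng) for f in per_pop])


def _ar1_latent(rng: np.random.Generator, n_hap: int, length: int, rho: float) -> np.ndarray:
    """Order-1 autoregressive standard-normal latents, shape (n_hap, length)."""
    z = np.empty((n_hap, length))
    z[:, 0] = rng.standard_normal(n_hap)
    if length > 1 and rho > 0.0:
        innov_sd = np.sqrt(1.0 - rho * rho)
        eps = rng.standard_normal((n_hap, length - 1))
        for t in range(1, length):
            z[:, t] = rho * z[:, t - 1] + innov_sd * eps[:, t - 1]
    elif length > 1:
        z[:, 1:] = rng.standard_normal((n_hap, length - 1))
    return z


def simulate_genotypes(
    freqs: np.ndarray,
    n: int,
    config: SimulationConfig,
    *,
    variant_meta: Optional[pd.DataFrame] = None,
    population: str = "POP",
    seed=None,
) -> GenotypePanel:
    """Diploid dosages with blockwise AR(1) LD at the given frequencies.

    Two latent haplotypes per individual follow an order-1 autoregressive
    Gaussian within each block (parameter ``block_rho``; blocks independent)
    and are thresholded at the allele-frequency quantile, so adjacent-SNP
    genotype correlation is positive within blocks and ~0 between blocks.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or freqs.shape[0] != config.n_variants:
        raise ValueError("freqs must be a length n_variants vector")
    if n < 2:
        raise ValueError("need at least 2 individuals")
    rng = _rng([config.seed, 103] if seed is None else seed)
    thr = ndtri(np.clip(freqs, 1e-12, 1 - 1e-12))
    dosage = np.empty((n, config.n_variants), dtype=np.float32)
    for start, stop in config.block_bounds():
        z = _ar1_latent(rng, 2 * n, stop - start, config.block_rho)
        hap = z < thr[start:stop]
        dosage[:, start:stop] = hap[:n].astype(np.float32) + hap[n:].astype(np.float32)
    vm = variant_table(config) if variant_meta is None else variant_meta.reset_index(drop=True)
    sm = pd.DataFrame(
        {
            "sample_id": [f"{population}_{i:06d}" for i in range(1, n + 1)],
            "population": population,
        }
    )
    return GenotypePanel(dosage, vm, sm, label=population)


def simulate_admixed(
    ancestral_freqs: np.ndarray,
    n: int,
    alpha: Sequence[float],
    config: SimulationConfig,
    *,
    variant_meta: Optional[pd.DataFrame] = None,
    population: str = "ADM",
    seed=None,
) -> GenotypePanel:
    """Admixed cohort: Dirichlet individual ancestry, block-level assignment.

    Each haplotype block of each haplotype is assigned one founder ancestry
    with the individual's Dirichlet proportions, then drawn from that
    founder's frequencies with the usual AR(1) within-block LD — mimicking
    admixture LD while preserving founder LD within blocks.
    """
    freqs = np.asarray(ancestral_freqs, dtype=float)
    if freqs.ndim != 2 or freqs.shape[0] < 2:
        raise ValueError("need frequencies for at least 2 ancestral populations")
    if freqs.shape[1] != config.n_variants:
        raise ValueError("frequency matrix must have n_variants columns")
    k = freqs.shape[0]
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape[0] != k or np.any(alpha < 0) or alpha.sum() <= 0:
        raise ValueError("alpha must be non-negative with a positive sum, one per population")
    if n < 2:
        raise ValueError("need at least 2 individuals")
    rng = _rng([config.seed, 104] if seed is None else seed)
    # Dirichlet with some alpha_i == 0: drop those components (mass zero).
    props = np.zeros((n, k))
    pos = alpha > 0
    props[:, pos] = rng.dirichlet(alpha[pos], size=n)
    hap_props = np.vstack([props, props])  # haplotype h of individual i = row i and i+n
    cum = np.cumsum(hap_props, axis=1)
    thr_all = ndtri(np.clip(freqs, 1e-12, 1 - 1e-12))
    dosage = np.empty((n, config.n_variants), dtype=np.float32)
    for start, stop in config.block_bounds():
        anc = (rng.random((2 * n, 1)) > cum).sum(axis=1)
        z = _ar1_latent(rng, 2 * n, stop - start, config.block_rho)
        hap = z < thr_all[anc, start:stop]
        dosage[:, start:stop] = hap[:n].astype(np.float32) + hap[n:].astype(np.float32)
    vm = variant_table(config) if variant_meta is None else variant_meta.reset_index(drop=True)
    sm = pd.DataFrame(
        {
            "sample_id": [f"{population}_{i:06d}" for i in range(1, n + 1)],
            "population": population,
        }
    )
    for j, (lab, _) in enumerate(config.populations[:k]):
        sm[f"anc_{lab}"] = props[:, j]
    return GenotypePanel(dosage, vm, sm, label=population)


def simulate_phenotype(
    panel: GenotypePanel,
    config: SimulationConfig,
    *,
    trait: Optional[TraitModel] = None,
    seed=None,
) -> TraitModel:
    """Attach an additive polygenic phenotype to ``panel`` (in place).

    When ``trait`` is None a new architecture is drawn: round(p_causal * M)
    causal variants chosen uniformly, standardized effects ~
    Normal(0, h2 / (M * p_causal)), converted to the per-allele scale by
    1/sqrt(2 f (1-f)) and rescaled so the realized genetic variance in this
    panel equals h2. Environmental noise is Normal(0, 1 - h2). Passing an
    existing ``trait`` applies the same per-allele effects to a new cohort
    (cross-ancestry genetic variance then floats with allele frequencies,
    as in real data). Returns the TraitModel used.
    """
    rng = _rng([config.seed, 105] if seed is None else seed)
    m = panel.n_variants
    x = panel.dosages.astype(np.float64, copy=False)
    if trait is None:
        n_causal = int(round(config.p_causal * m))
        if n_causal < 1:
            raise ValueError("p_causal * n_variants must be at least 1")
        causal = np.sort(rng.choice(m, size=n_causal, replace=False))
        a = np.zeros(m)
        if config.h2 > 0:
            std_eff = rng.normal(0.0, np.sqrt(config.h2 / n_causal), size=n_causal)
            f = np.clip(panel.allele_frequencies()[causal], 1e-4, 1 - 1e-4)
            a[causal] = std_eff / np.sqrt(2.0 * f * (1.0 - f))
            g = x[:, causal] @ a[causal]
            sd = g.std()
            if sd > 0:
                a[causal] *= np.sqrt(config.h2) / sd
        trait = TraitModel(causal, a, float(np.sqrt(1.0 - config.h2)))
    g = x @ trait.effects_per_allele
    g -= g.mean()
    panel.phenotype = g + rng.normal(0.0, trait.env_sd, size=panel.n_samples)
    return trait


def simulate_gwas(panel: GenotypePanel, min_maf: float = 0.0):
    """Marginal per-SNP GWAS: simple linear regression of phenotype on dosage.

    Returns a :class:`transprs.sumstats.SummaryStats` with beta, SE, p, N and
    the effect-allele (allele_b) frequency. Monomorphic variants keep a row
    with missing beta and flag ``monomorphic`` rather than being dropped.
    """
    from transprs.sumstats import SummaryStats

    if panel.phenotype is None:
        raise ValueError("panel has no phenotype; run simulate_phenotype first")
    x = panel.dosages.astype(np.float64, copy=False)
    y = np.asarray(panel.phenotype, dtype=float)
    n = panel.n_samples
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = yc @ xc
    syy = float(yc @ yc)
    poly = sxx > 0
    beta = np.full(panel.n_variants, np.nan)
    se = np.full(panel.n_variants, np.nan)
    pval = np.full(panel.n_variants, np.nan)
    beta[poly] = sxy[poly] / sxx[poly]
    sse = np.maximum(syy - beta[poly] * sxy[poly], 0.0)
    sigma2 = sse / (n - 2)
    se[poly] = np.sqrt(np.maximum(sigma2 / sxx[poly], 1e-300))
    tstat = beta[poly] / se[poly]
    pval[poly] = np.clip(2.0 * stats.t.sf(np.abs(tstat), df=n - 2), 1e-300, 1.0)
    df = panel.variant_meta[["variant_id", "chrom", "pos"]].copy()
    df["effect_allele"] = panel.variant_meta["allele_b"].to_numpy()
    df["other_allele"] = panel.variant_meta["allele_a"].to_numpy()
    df["eaf"] = x.mean(axis=0) / 2.0
    df["beta"] = beta
    df["se"] = se
    df["p"] = pval
    df["n"] = n
    df["flag"] = np.where(poly, "", "monomorphic")
    return SummaryStats(df)
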