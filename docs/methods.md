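# Methods

## Posterior-mean SNP weights

The weight engine treats the GWAS marginal effects on the standardized
scale, `b_j = z_j / sqrt(N)` with `z_j = beta_j / se_j`. This equals the
correlation between standardized genotype and phenotype up to `O(1/N)`
regardless of the trait units the GWAS used, which is why the engine is
insensitive to whether the original phenotype was raw or inverse-normal
transformed (the simulator standardizes its phenotype to unit variance).

Under the infinitesimal prior every variant is causal with
`beta_j ~ N(0, h2/M)`; the posterior mean per LD window *w* is the ridge-type
solve `(M/(N h2) I + D_w)^(-1) b_w`. Under the point-normal prior a variant
is causal with probability *p*; the single-site Gibbs sampler sweeps variants
in position order, residualizes each marginal effect against the current
state of its window, and samples indicator and effect from the conditional
posterior (formulas in the README). The reported weight is the
Rao-Blackwellized average of `pbar_j * mu_j` over post-burn-in sweeps, which
has strictly lower Monte-Carlo variance than averaging the sampled effects
and is exact in the no-LD limit. Sampled inclusion indicators are still
tracked (and tested) so the chain's ergodicity is exercised, not just the
conditional means.

Numerical choices:

* `h2` is an operator input (default 0.25, matching the simulated trait);
  estimating it (e.g. by LD-score regression) is out of scope.
* `n_iter = 200`, `n_burn = 40` by default; the no-LD oracle agreement is
  reached well within this budget. Oracle tests use 2000 sweeps so
  Monte-Carlo error sits comfortably below the 2% comparison bands.
* Divergence guard: if a sweep's mean |beta| exceeds 10x the prior budget
  `sqrt(h2/M)`, the window restarts with a more strongly shrunk LD matrix
  (in +0.1 increments) and warns.
* Per-window seeds derive from the config seed via `SeedSequence`, so runs
  are bit-reproducible; the sweep kernel is compiled with numba.
* Back-conversion to per-allele units divides by `sqrt(2 f (1-f))` using the
  LD reference panel's frequencies (scoring is panel-consistent); weights at
  monomorphic reference variants are set to zero. When GWAS and panel
  frequencies diverge strongly the per-allele scale inherits that
  divergence — a documented risk of any external-panel workflow.

## LD references

Windowed Pearson correlation on mean-imputed dosages, with consecutive
windows of `max(50, 2*round(M/3000))` variants (the conventional
radius-M/3000 locality approximation with a 50-SNP floor at desk scale) and
ridge shrinkage `(1 - lambda) R + lambda I`, `lambda = 0.01` by default —
enough to keep every window positive definite with 2500-sample panels.
Cross-window LD is treated as zero. Monomorphic variants get zero
off-diagonals and a warning.

Ancestry assignment projects target individuals onto reference-panel
principal components (Patterson scaling `sqrt(2 f (1-f))` with reference
frequencies, loadings from the reference only) and labels by nearest
population centroid. Panel selection takes up to `max_n` labelled
individuals (2500 by default, the panel size of the original design),
deterministically under a seed. The trans-ethnic panel is an unweighted
row-concatenation of the per-population panels.

A property worth knowing: pooling attenuates genuinely correlated pairs
(heterogeneous variances dilute shared correlation) but *inflates*
near-zero pairs, because between-population allele-frequency differences act
as a shared mixture component (Wahlund effect) that manufactures spurious
LD. The attenuation test therefore conditions on pairs with substantial
within-population LD.

## Synthetic data

The generator reproduces the statistical features the pipeline relies on,
not sequence-level realism:

* **Divergence** — Balding-Nichols: ancestral frequencies Uniform(0.05,
  0.95), population frequencies Beta-distributed with mean `p0` and variance
  `F p0 (1-p0)`. The config stores pairwise F_ST; per-population divergence
  from the shared ancestral pool solves `F_i + F_j ~ F_ij` by least squares.
  Default pairwise F_ST 0.12 for three founder populations, roughly the
  continental range.
* **LD** — within each of 40 equal blocks, haplotypes are thresholded
  order-1 autoregressive latent Gaussians (`block_rho = 0.6` by default);
  blocks are independent. This gives tunable, window-compatible local
  correlation without recombination maps. All populations share the same
  latent process, so cross-population LD differences arise only through
  allele frequencies — see Limitations.
* **Admixture** — per-individual Dirichlet ancestry proportions; each
  haplotype block draws one ancestral origin, preserving founder LD within
  blocks and mimicking admixture LD at the mixture level.
* **Phenotype** — `round(p_causal * M)` causal variants, standardized
  effects `N(0, h2/(M p_causal))` converted to per-allele units and rescaled
  so realized genetic variance equals `h2` in the panel where the trait is
  drawn; environmental noise `N(0, 1 - h2)`. The same per-allele effects are
  applied to the other cohorts, so their realized genetic variance floats
  with allele frequencies as in real data.
* **GWAS** — per-variant simple linear regression (beta, SE, t-based p,
  N, effect-allele frequency); monomorphic variants are flagged, not
  dropped. Default N = 20 000 (the original GWAS's 339 224 scaled down to
  desk size), M = 2000, p_causal = 0.03, h2 = 0.25, LD panels of 2500 and
  target cohorts of 2000 — sizes chosen so ten full replicates run in a few
  minutes on one CPU.

## Harmonization and scoring

Summary statistics are matched to a reference by variant id; exact matches
are kept, swapped alleles negate the effect and complement the frequency,
strand-complement matches flip alleles, and strand-ambiguous pairs (A/T,
C/G) are dropped when MAF > 0.40 and otherwise resolved by frequency
agreement with the reference (by literal letters when no reference frequency
exists). Report categories are disjoint and partition the input; a
flip+swap combination counts as a swap (the sign-bearing event). The same
engine aligns weight files to target cohorts before scoring; under 50%
matched weights is treated as a cohort/weight-set mismatch and refused.
Missing dosages are mean-imputed with the *cohort* frequency — a per-site
decision in the federated design — which shifts every score by a constant
and cannot change ranks. Scores are not centred or standardized by default
(AUC is rank-based); a flag provides z-scored output.

## Evaluation

Cases are the top 1% or 5% of the within-cohort phenotype distribution
(linear-interpolation quantile, strictly-greater rule: threshold ties are
controls). AUC is the Mann-Whitney statistic with midrank ties; its 95% CI
comes from the DeLong variance (deterministic, no bootstrap). Logistic
regression standardizes the score to unit variance so effects are comparable
across weight sets, with a ridge-penalized fallback (flagged) under perfect
separation; linear regression reports the slope p-value and r² = squared
Pearson correlation as variance explained. Comparison tables are fractions x
LD panels with the best fraction flagged per panel; panel comparisons in the
replicated study use each panel's best ("most informative") fraction.

## Pipeline

One config drives simulate -> build-LD -> train -> score -> evaluate, with
per-stage seeds derived from the master seed by fixed offsets, stage-scoped
error reporting, and a manifest of config hash, versions, file digests and
wall-clock per stage. Default panels are EUR, ASN, AFR, an admixed (ADM)
panel, and the pooled trans-ethnic (TE) panel — 5 panels x 8 fractions = 40
weight sets. The exported site bundle (weight TSVs + manifest +
instructions) is sufficient for a collaborating site to reproduce scoring
bit-for-bit.

## What the simulation does and does not show

Passing tests demonstrate that the solver and sampler are correct against
closed forms, that harmonization and scoring are orientation-invariant, that
the evaluation layer is exact against brute force, and that the end-to-end
workflow is deterministic and portable in the federated sense. The
simulation's cross-ancestry behaviour is more conservative than real data in
two respects. First, per-causal-variant power at desk scale
(`N h2 / (M p) ~ 83`) is far higher than in a million-SNP GWAS (~2), so all
mixture fractions recover essentially the same causal set and the AUC
profile across fractions is nearly flat, without the sharp optimum at the
true causal fraction or the collapse at very small fractions seen at real
scale. Second, because every population shares the same latent LD process,
the training population's own LD panel is already the correct deconvolution
matrix in every target cohort; pooled trans-ethnic LD then matches it to
within ~0.02 AUC (the no-loss property) but has no mechanism to beat it.
Observing a genuine trans-ethnic *advantage* would require
population-specific LD structure (different block boundaries or
correlation strengths), which this generator deliberately does not model.

## Known limitations

No recombination maps, sex chromosomes, genotyping error or imputation
uncertainty; no INDELs, multi-allelic variants or genome-build liftover; no
in-package h2 estimation; cM-based LD windows unsupported. The MHC exclusion
default (chr6:25-34 Mb) covers the extended region; the coordinate build
follows the input.
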