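"""Posterior-mean SNP weights from summary statistics and windowed LD.

Two estimators of the posterior mean effect size given standardized
marginal effects b (= z/sqrt(N)) and a windowed LD matrix D:

* infinitesimal prior — closed form: per window solve
  (M/(N h2) I + D) x = b;
* point-normal (spike-and-slab) prior — per-variant Gibbs sampling: with
  mixture probability p a variant's standardized effect is
  Normal(0, h2/(M p)), otherwise exactly zero. Each sweep residualizes the
  marginal effect against the current effects of the other variants in the
  window, then samples the inclusion indicator and the slab effect from
  their conditional posterior. The reported weight is the average posterior
  mean over post-burn-in sweeps.

Weights are returned on the per-allele scale (standardized weight divided
by sqrt(2 f (1-f)) with reference-panel frequencies f), ready for dosage
scoring.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from numba import njit

from transprs.ldref import LDReference

__all__ = ["TrainConfig", "WeightSet", "ldpred_inf", "ldpred_gibbs", "train_all", "DEFAULT_FRACTIONS"]

#: Mixture probabilities swept by the workflow: infinitesimal prior plus
#: seven point-normal fractions of causal markers.
DEFAULT_FRACTIONS: tuple = ("inf", 1.0, 0.3, 0.1, 0.03, 0.01, 0.003, 0.001)


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the weight engine.

    ``h2`` is the assumed SNP heritability of the trait (an external input;
    it is not estimated here) and ``n_gwas`` the effective GWAS sample size.
    """

    n_gwas: int
    h2: float = 0.25
    fractions: tuple = DEFAULT_FRACTIONS
    n_iter: int = 200
    n_burn: int = 40
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.h2 < 1.0):
            raise ValueError("h2 must be in (0, 1)")
        if self.n_gwas < 2:
            raise ValueError("n_gwas must be at least 2")
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be smaller than n_iter")
        for f in self.fractions:
            if f != "inf" and not (0.0 < float(f) <= 1.0):
                raise ValueError("every non-inf fraction must be in (0, 1]")


@dataclass
class WeightSet:
    """Posterior-mean per-allele SNP weights for one (LD panel, fraction).

    ``df`` columns: variant_id, chrom, pos, effect_allele, other_allele,
    weight (+ freq, the reference frequency used for scale conversion).
    """

    df: pd.DataFrame
    fraction: Union[str, float]
    ld_panel: str
    scale: str = "per-allele"

    def __post_init__(self):
        if not np.all(np.isfinite(self.df["weight"].to_numpy())):
            raise ValueError("weights must be finite")

    @property
    def fraction_label(self) -> str:
        return "inf" if self.fraction == "inf" else f"{float(self.fraction):g}"

    def weights(self) -> np.ndarray:
        return self.df["weight"].to_numpy()

    def to_standardized(self) -> np.ndarray:
        """Weights on the standardized-genotype scale (round-trip exact)."""
        if self.scale == "standardized":
            return self.weights()
        f = self.df["freq"].to_numpy()
        return self.weights() * np.sqrt(2.0 * f * (1.0 - f))

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, fraction, ld_panel) -> "WeightSet":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}), fraction, ld_panel)


def _per_allele(std_weights: np.ndarray, freqs: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    f = np.clip(np.asarray(freqs, dtype=float), 0.0, 1.0)
    denom = np.sqrt(2.0 * f * (1.0 - f))
    out = np.zeros_like(std_weights)
    ok = denom > 0
    out[ok] = std_weights[ok] / denom[ok]
    return out, f


def _weight_frame(ld: LDReference, per_allele: np.ndarray, freqs: np.ndarray) -> pd.DataFrame:
    vm = ld.variant_meta
    return pd.DataFrame(
        {
            "variant_id": vm["variant_id"].to_numpy(),
            "chrom": vm["chrom"].to_numpy(),
            "pos": vm["pos"].to_numpy(),
            "effect_allele": vm["allele_b"].to_numpy(),
            "other_allele": vm["allele_a"].to_numpy(),
            "weight": per_allele,
            "freq": freqs,
        }
    )


def ldpred_inf(std_effects: np.ndarray, ld: LDReference, cfg: TrainConfig) -> WeightSet:
    """Infinitesimal-prior posterior mean: windowed ridge-type linear solve.

    Per window w with LD matrix D_w: x_w = (M/(N h2) I + D_w)^{-1} b_w,
    where M is the total variant count. The N -> infinity limit recovers the
    joint (deconvolved) effects D^{-1} b.
    """
    b = np.asarray(std_effects, dtype=float)
    m = ld.n_variants
    if b.shape[0] != m:
        raise ValueError("std_effects length does not match the LD reference")
    ridge = m / (cfg.n_gwas * cfg.h2)
    x = np.empty(m)
    for (a, bnd), d in zip(ld.windows, ld.matrices):
        mat = d + ridge * np.eye(bnd - a)
        try:
            x[a:bnd] = np.linalg.solve(mat, b[a:bnd])
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular LD system in window [{a}, {bnd}); increase shrinkage_lambda"
            ) from err
    w, f = _per_allele(x, ld.freqs)
    return WeightSet(_weight_frame(ld, w, f), "inf", ld.label)


@njit(cache=True)
def _gibbs_window(D, b, n_gwas, sigma2, p, n_iter, n_burn, seed, guard):  # pragma: no cover
    """Single-window Gibbs sweep; returns (posterior mean, mean inclusion, diverged)."""
    np.random.seed(seed)
    m = b.shape[0]
    beta = np.zeros(m)
    post = np.zeros(m)
    incl = np.zeros(m)
    shrink = 1.0 / (1.0 + 1.0 / (n_gwas * sigma2))  # = 1/(1 + M p/(N h2))
    tau = math.sqrt(shrink / n_gwas)
    all_in = p >= 1.0
    log_odds = 0.0
    if not all_in:
        log_odds = math.log((1.0 - p) / p) + 0.5 * math.log(1.0 + n_gwas * sigma2)
    kept = n_iter - n_burn
    diverged = False
    for it in range(n_iter):
        sweep_abs = 0.0
        for j in range(m):
            r = b[j] - (np.dot(D[j], beta) - beta[j])  # D has unit diagonal
            mu = shrink * r
            if all_in:
                pbar = 1.0
            else:
                t = log_odds - 0.5 * n_gwas * mu * r
                if t > 35.0:
                    pbar = math.exp(-t)
                elif t < -35.0:
                    pbar = 1.0
                else:
                    pbar = 1.0 / (1.0 + math.exp(t))
            included = np.random.random() < pbar
            if included:
                beta[j] = mu + tau * np.random.normal()
            else:
                beta[j] = 0.0
            sweep_abs += abs(beta[j])
            if it >= n_burn:
                post[j] += pbar * mu
                if included:
                    incl[j] += 1.0
        if sweep_abs / m > guard:
            diverged = True
            break
    return post / kept, incl / kept, diverged


def ldpred_gibbs(
    std_effects: np.ndarray,
    ld: LDReference,
    cfg: TrainConfig,
    fraction: float,
    *,
    return_inclusion: bool = False,
):
    """Spike-and-slab Gibbs posterior-mean weights at mixture probability p.

    Per sweep and variant j the marginal effect is residualized against the
    current effects of the other variants in its window
    (b'_j = b_j - sum_k D_jk beta_k), the slab posterior is
    Normal(b'_j/(1 + M p/(N h2)), (1/N)/(1 + M p/(N h2))) and the inclusion
    probability is the usual two-Gaussian Bayes factor. The returned weight
    is the Rao-Blackwellized average of pbar_j * mu_j over kept sweeps.

    If a sweep's mean |beta| exceeds 10x the prior per-SNP SD budget
    sqrt(h2/M) the chain is restarted with a more strongly shrunk LD matrix
    (divergence guard), with a warning.
    """
    p = float(fraction)
    if not (0.0 < p <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    b = np.asarray(std_effects, dtype=float)
    m = ld.n_variants
    if b.shape[0] != m:
        raise ValueError("std_effects length does not match the LD reference")
    sigma2 = cfg.h2 / (m * p)
    guard = 10.0 * math.sqrt(cfg.h2 / m)
    ss = np.random.SeedSequence([cfg.seed, int(round(p * 1_000_000))])
    window_seeds = ss.generate_state(len(ld.windows)) % (2**31 - 1)
    x = np.empty(m)
    incl = np.empty(m)
    for i, ((a, bnd), d) in enumerate(zip(ld.windows, ld.matrices)):
        dmat = np.ascontiguousarray(d, dtype=np.float64)
        extra = 0.0
        while True:
            post_w, incl_w, diverged = _gibbs_window(
                dmat,
                b[a:bnd],
                float(cfg.n_gwas),
                sigma2,
                p,
                cfg.n_iter,
                cfg.n_burn,
                int(window_seeds[i]),
                guard,
            )
            if not diverged:
                break
            extra += 0.1
            if extra > 0.95:
                raise RuntimeError("Gibbs sampler diverged even under maximal LD shrinkage")
            warnings.warn(
                f"Gibbs divergence in window [{a}, {bnd}) at p={p}; "
                f"restarting with extra shrinkage {extra:.1f}",
                stacklevel=2,
            )
            dmat = (1.0 - extra) * np.asarray(d) + extra * np.eye(bnd - a)
        x[a:bnd] = post_w
        incl[a:bnd] = incl_w
    w, f = _per_allele(x, ld.freqs)
    ws = WeightSet(_weight_frame(ld, w, f), p, ld.label)
    if return_inclusion:
        return ws, incl
    return ws


def train_all(
    std_effects: np.ndarray,
    ld_panels: Sequence[LDReference],
    cfg: TrainConfig,
) -> Dict[Tuple[str, str], WeightSet]:
    """All (LD panel x mixture fraction) weight sets, keyed by labels.

    The workflow of the study: five LD panels x eight fractions = forty
    weight sets. Panels and summary statistics must be pre-aligned to the
    same variant list.
    """
    b = np.asarray(std_effects, dtype=float)
    ids0 = None
    for ld in ld_panels:
        ids = ld.variant_meta["variant_id"].to_numpy()
        if ld.n_variants != b.shape[0]:
            raise ValueError(f"panel '{ld.label}' variant count does not match std_effects")
        if ids0 is None:
            ids0 = ids
        elif not np.array_equal(ids, ids0):
            raise ValueError("LD panels are not aligned to a common variant list")
    out: Dict[Tuple[str, str], WeightSet] = {}
    for ld in ld_panels:
        for frac in cfg.fractions:
            if frac == "inf":
                ws = ldpred_inf(b, ld, cfg)
            else:
                ws = ldpred_gibbs(b, ld, cfg, float(frac))
            out[(ld.label, ws.fraction_label)] = ws
    return out
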