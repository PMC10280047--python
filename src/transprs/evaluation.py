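"""Extreme-percentile case definition, ROC/AUC, association, panel comparison.

The evaluation follows the study design for a continuous trait scored in
many cohorts: the top 1% / 5% of the within-cohort phenotype distribution
are cases, the rest controls; each score column is assessed by Mann-Whitney
AUC with a DeLong 95% CI, logistic regression of case status on the
standardized score, and linear regression against the continuous phenotype
(variance explained = squared Pearson correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvaluationResult",
    "define_extreme_cases",
    "roc_auc",
    "logistic_assoc",
    "linear_assoc",
    "evaluate_scores",
    "compare_panels",
]


@dataclass
class EvaluationResult:
    """AUC, association statistics and variance explained for one score."""

    cohort: str
    percentile: float
    ld_panel: str
    fraction: str
    auc: float
    auc_ci: Tuple[float, float]
    p_logistic: float
    p_linear: float
    r2: float
    n_cases: int
    n_controls: int

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["auc_ci_low"], d["auc_ci_high"] = d.pop("auc_ci")
        return d


def define_extreme_cases(phenotype: np.ndarray, percentile: float) -> np.ndarray:
    """Binary labels: case iff phenotype exceeds the (100-percentile) quantile.

    The quantile uses linear interpolation; individuals exactly at the
    threshold are controls (strict inequality). Raises when no case exists
    (e.g. a constant phenotype).
    """
    y = np.asarray(phenotype, dtype=float)
    if not (0.0 < percentile < 50.0):
        raise ValueError("percentile must be in (0, 50)")
    q = np.quantile(y, 1.0 - percentile / 100.0)
    labels = y > q
    if labels.sum() == 0:
        raise ValueError("no cases above the percentile threshold (degenerate phenotype?)")
    return labels


def _delong_variance(cases: np.ndarray, controls: np.ndarray) -> float:
    """DeLong variance of the midrank AUC estimator."""
    m, n = len(cases), len(controls)
    all_scores = np.concatenate([cases, controls])
    ranks = stats.rankdata(all_scores)
    ranks_cases = stats.rankdata(cases)
    ranks_controls = stats.rankdata(controls)
    # structural components (Sun & Xu fast DeLong)
    v10 = (ranks[:m] - ranks_cases) / n
    v01 = 1.0 - (ranks[m:] - ranks_controls) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, Tuple[float, float]]:
    """Mann-Whitney AUC with midrank ties and a DeLong 95% CI.

    AUC is the probability a random case outscores a random control (ties
    count 1/2). A constant score yields AUC 0.5 with a degenerate CI and a
    warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    cases, controls = scores[labels], scores[~labels]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("need at least one case and one control")
    if scores.std() == 0:
        warnings.warn("constant score: AUC undefined, reporting 0.5", stacklevel=2)
        return 0.5, (0.5, 0.5)
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - len(cases) * (len(cases) + 1) / 2.0) / (len(cases) * len(controls))
    var = _delong_variance(cases, controls)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return float(auc), ci


def logistic_assoc(
    score: np.ndarray,
    labels: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> dict:
    """Maximum-likelihood logistic regression of case status on the score.

    The score is standardized to unit variance so effects are comparable
    across weight sets. Perfect or quasi-perfect separation falls back to a
    ridge-penalized fit (flagged), with Wald statistics from the observed
    information at the penalized estimate.
    """
    import statsmodels.api as sm

    y = np.asarray(labels, dtype=float)
    s = np.asarray(score, dtype=float)
    sd = s.std()
    if sd == 0:
        raise ValueError("constant score")
    s = (s - s.mean()) / sd
    design = [np.ones_like(s), s]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(s):
            cov = cov.T
        design.extend(cov.T)
    x = np.column_stack(design)
    flag = ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, x).fit(disp=False)
        beta, se = fit.params[1], fit.bse[1]
    except Exception:
        flag = "penalized"
        model = sm.Logit(y, x)
        fit = model.fit_regularized(alpha=1.0, L1_wt=0.0, disp=False, maxiter=500)
        params = np.asarray(fit.params)
        hess = model.hessian(params) - 2.0 * np.eye(x.shape[1])
        cov_p = np.linalg.inv(-hess)
        beta, se = params[1], np.sqrt(cov_p[1, 1])
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return {"beta": float(beta), "se": float(se), "p": float(max(p, 1e-300)), "flag": flag}


def linear_assoc(score: np.ndarray, phenotype: np.ndarray) -> dict:
    """Simple least squares of the continuous phenotype on the score.

    Returns the slope, its t-test p-value and r2 (squared Pearson
    correlation = variance explained by the score).
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if s.std() == 0:
        raise ValueError("constant score")
    fit = stats.linregress(s, y)
    return {
        "beta": float(fit.slope),
        "p": float(max(fit.pvalue, 1e-300)),
        "r2": float(fit.rvalue**2),
    }


def evaluate_scores(
    score_table,
    phenotype: np.ndarray,
    *,
    cohort: str = "cohort",
    percentiles: Sequence[float] = (1.0, 5.0),
) -> List[EvaluationResult]:
    """Evaluate every score column at every extreme percentile."""
    results = []
    y = np.asarray(phenotype, dtype=float)
    for pct in percentiles:
        labels = define_extreme_cases(y, pct)
        for col in score_table.score_columns:
            s = score_table.scores(col)
            panel, _, frac = col.partition(":")
            auc, ci = roc_auc(s, labels)
            logi = logistic_assoc(s, labels)
            lin = linear_assoc(s, y)
            results.append(
                EvaluationResult(
                    cohort=cohort,
                    percentile=pct,
                    ld_panel=panel,
                    fraction=frac,
                    auc=auc,
                    auc_ci=ci,
                    p_logistic=logi["p"],
                    p_linear=lin["p"],
                    r2=lin["r2"],
                    n_cases=int(labels.sum()),
                    n_controls=int((~labels).sum()),
                )
            )
    return results


def compare_panels(results: Iterable[EvaluationResult]) -> pd.DataFrame:
    """Long-to-wide AUC table: rows fractions, columns LD panels.

    All results must share cohort and percentile. The best fraction per
    panel column is recorded in ``table.attrs['best']``, mirroring the
    study's per-panel "most informative fraction" comparisons.
    """
    res = list(results)
    if not res:
        raise ValueError("no results to compare")
    keys = {(r.cohort, r.percentile) for r in res}
    if len(keys) > 1:
        raise ValueError(f"results mix cohorts/percentiles: {sorted(keys)}")
    long = pd.DataFrame([{"fraction": r.fraction, "ld_panel": r.ld_panel, "auc": r.auc} for r in res])
    order = list(dict.fromkeys(long["fraction"]))
    table = long.pivot(index="fraction", columns="ld_panel", values="auc").loc[order]
    table.attrs["cohort"], table.attrs["percentile"] = next(iter(keys))
    table.attrs["best"] = {col: table[col].idxmax() for col in table.columns}
    return table
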