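"""Discrimination and association statistics for score validation.

AUROC as the Mann-Whitney statistic computed from midranks (the natural
convention for heavily tied integer scores), with either DeLong
(structural-components) or stratified-bootstrap confidence intervals;
score-stratified outcome tables; Woolf 2x2 odds ratios with
Haldane-Anscombe correction; and multivariable logistic regression with
Wald intervals for adjusted odds ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .adhoc import adhoc_score
from .records import PatientRecord


@dataclass(frozen=True)
class RocResult:
    auroc: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_pos: int
    n_neg: int
    method: str


@dataclass(frozen=True)
class OddsRatioResult:
    estimate: float
    ci_low: float
    ci_high: float
    method: str
    label: str = ""


def _check_labels(scores: np.ndarray, labels: np.ndarray) -> tuple[int, int]:
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "AUROC requires at least one positive and one negative label "
            f"(got {n_pos} positives, {n_neg} negatives)")
    return n_pos, n_neg


def auroc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Area under the ROC curve by midranks.

    Equals the Mann-Whitney statistic (concordant pairs + half the tied
    pairs, over all positive-negative pairs): the probability that a random
    positive outranks a random negative, with ties split.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_labels(s, y)
    ranks = stats.rankdata(s)  # midranks
    rank_sum_pos = ranks[y == 1].sum()
    auc = (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return RocResult(float(auc), None, None, n_pos, n_neg, "mann_whitney")


def _delong_variance(s: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(auc, variance) via the structural-components estimator.

    Placement values are computed from midranks in O(n log n): for positive
    i, V10_i is the fraction of negatives it beats (ties half); var(AUC) =
    S10/m + S01/n with the usual unbiased component variances.
    """
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def auroc_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    method: str = "delong",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> RocResult:
    """AUROC with a confidence interval.

    ``delong`` — normal-approximation interval from the DeLong variance,
    truncated to [0, 1] (deterministic).  ``bootstrap`` — percentile
    interval over class-stratified resamples; a degenerate resample cannot
    occur because resampling is stratified within each class.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_labels(s, y)
    if method == "delong":
        auc, var = _delong_variance(s, y)
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * math.sqrt(max(var, 0.0))
        return RocResult(auc, max(0.0, auc - half), min(1.0, auc + half),
                         n_pos, n_neg, "delong")
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos = s[y == 1]
        neg = s[y == 0]
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            bs = np.concatenate([
                rng.choice(pos, size=n_pos, replace=True),
                rng.choice(neg, size=n_neg, replace=True),
            ])
            by = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
            aucs[b] = auroc(bs, by).auroc
        alpha = 1.0 - level
        lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
        point = auroc(s, y).auroc
        return RocResult(point, float(lo), float(hi), n_pos, n_neg, "bootstrap")
    raise ValueError(f"unknown CI method {method!r}")


# ---------------------------------------------------------------------------
# stratified outcomes


def stratified_outcomes(
    records: Sequence[PatientRecord],
    scores: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Outcome table stratified by score value 0..4.

    Columns: n, deaths, mortality, mof_cases, mof_rate, mean_icu_los,
    mean_hosp_los.  Rates over records with the outcome observed; empty
    strata keep n = 0 with NaN rates (absence of evidence, not a 0% rate).
    Scores are computed with :func:`adhocscore.adhoc.adhoc_score` unless
    supplied.
    """
    if scores is None:
        scores = [adhoc_score(r).score for r in records]
    scores = np.asarray(scores, dtype=int)
    rows = []
    for k in range(5):
        sel = [r for r, s in zip(records, scores) if s == k]
        died = [r.died for r in sel if r.died is not None]
        mof = [r.mof for r in sel if r.mof is not None]
        icu = [r.icu_los for r in sel if r.icu_los is not None]
        hosp = [r.hosp_los for r in sel if r.hosp_los is not None]
        rows.append({
            "score": k,
            "n": len(sel),
            "deaths": int(sum(died)) if died else 0,
            "mortality": sum(died) / len(died) if died else math.nan,
            "mof_cases": int(sum(mof)) if mof else 0,
            "mof_rate": sum(mof) / len(mof) if mof else math.nan,
            "mean_icu_los": float(np.mean(icu)) if icu else math.nan,
            "mean_hosp_los": float(np.mean(hosp)) if hosp else math.nan,
        })
    return pd.DataFrame(rows).set_index("score")


# ---------------------------------------------------------------------------
# odds ratios


def odds_ratio_2x2(a: int, b: int, c: int, d: int, level: float = 0.95) -> OddsRatioResult:
    """Odds ratio (a*d)/(b*c) with the Woolf log-SE interval.

    Layout: a = exposed cases, b = exposed non-cases, c = unexposed cases,
    d = unexposed non-cases.  Any zero cell triggers the Haldane-Anscombe
    correction (0.5 added to every cell), flagged in the method label; two
    zeros on a diagonal leave the OR undefined and raise ``ValueError``.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        raise ValueError("odds ratio undefined: both cells of a diagonal are zero")
    method = "woolf_2x2"
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        method = "woolf_2x2_haldane"
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return OddsRatioResult(est, est * math.exp(-z * se), est * math.exp(z * se), method)


class SeparationError(RuntimeError):
    """Perfect (or quasi-) separation: the logistic MLE does not exist."""


def fit_logistic(
    design: np.ndarray,
    outcome: Sequence[int],
    labels: Optional[Sequence[str]] = None,
    add_intercept: bool = True,
    level: float = 0.95,
) -> list[OddsRatioResult]:
    """Multivariable logistic regression; per-coefficient odds ratios.

    Maximum likelihood via iteratively reweighted least squares, Wald
    intervals from the inverse observed information, exponentiated to the
    OR scale.  The intercept's "OR" is the baseline odds.  Raises
    :class:`SeparationError` when a coefficient diverges (|beta| > 15),
    ``ValueError`` on rank deficiency or too few rows.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcome, dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        labels = ["intercept"] + list(labels) if labels is not None else None
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than coefficients")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    fit = model.fit(maxiter=100, tol=1e-8)
    beta = fit.params
    if np.any(np.abs(beta) > 15):
        raise SeparationError(
            "a coefficient exceeded |15|: data are (quasi-)separated; "
            "consider a penalized fit")
    se = np.sqrt(np.diag(fit.cov_params()))
    z = stats.norm.ppf(0.5 + level / 2.0)
    if labels is None:
        labels = [f"x{j}" for j in range(X.shape[1])]
    return [
        OddsRatioResult(
            math.exp(beta[j]),
            math.exp(beta[j] - z * se[j]),
            math.exp(beta[j] + z * se[j]),
            "logistic_wald",
            labels[j],
        )
        for j in range(X.shape[1])
    ]


__all__ = [
    "RocResult",
    "OddsRatioResult",
    "SeparationError",
    "auroc",
    "auroc_ci",
    "stratified_outcomes",
    "odds_ratio_2x2",
    "fit_logistic",
]
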