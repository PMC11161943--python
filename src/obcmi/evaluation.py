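"""Predictive-performance statistics for an integer risk score.

Covers the full evaluation of a comorbidity score against a binary
outcome:

* per-unit logistic odds ratios with Wald confidence intervals,
* Wilcoxon rank-sum comparison of score distributions between outcome
  groups (exact enumeration for tiny groups, tie-corrected normal
  approximation otherwise),
* ROC curves and AUC with DeLong confidence intervals, plus the paired
  DeLong test for comparing two scoring systems on the same subjects,
* per-cutoff classification tables (sensitivity, specificity, predictive
  values, correct classification),
* 2x2 effect measures: risk difference in percentage points, risk ratio
  with log-scale Wald interval, and the number needed to harm
  NNH = 100 / RD%,
* two-sided normal-approximation power for a difference of two
  independent proportions,
* cumulative score-frequency tables.

Percentages follow table style: full precision is retained internally and
:func:`round_percent` rounds half away from zero to one decimal for
reports.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "LogisticFit",
    "GroupComparison",
    "ROCResult",
    "CutoffEvaluation",
    "fit_per_unit_logistic",
    "wilcoxon_rank_sum",
    "roc_auc",
    "compare_auc_paired",
    "cutoff_table",
    "two_by_two_stats",
    "power_two_proportions",
    "cumulative_frequency",
    "round_percent",
]


def round_percent(x: float | None, ndigits: int = 1) -> float | None:
    """Round half away from zero (table style); passes ``None`` through."""
    if x is None:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _as_binary(outcome) -> np.ndarray:
    y = np.asarray(outcome)
    if y.dtype != bool:
        vals = np.unique(y)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("outcome must be binary (bool or 0/1)")
        y = y.astype(bool)
    return y


def _require_both_classes(y: np.ndarray) -> None:
    if y.all() or not y.any():
        raise ValueError("outcome has a single class; both classes are required")


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticFit:
    """Per-unit logistic fit ``logit P(y=1) = beta0 + beta1 * score``."""

    beta0: float
    beta1: float
    se_beta1: float
    or_per_unit: float
    ci_low: float
    ci_high: float
    wald_p: float
    converged: bool
    n: int


def _logistic_newton_polish(
    x: np.ndarray, y: np.ndarray, beta: np.ndarray, tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-polish an MLE to gradient norm < tol; returns (beta, cov, ok)."""
    X = np.column_stack([np.ones_like(x), x])
    for _ in range(50):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.linalg.norm(grad) < tol:
            break
        W = mu * (1 - mu)
        hess = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, np.full((2, 2), np.nan), False
        beta = beta + step
    eta = X @ beta
    mu = expit(eta)
    ok = np.linalg.norm(X.T @ (y - mu)) < max(tol, 1e-6)
    W = mu * (1 - mu)
    hess = X.T @ (X * W[:, None])
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return beta, np.full((2, 2), np.nan), False
    return beta, cov, ok


def fit_per_unit_logistic(scores, outcome) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome on score.

    Fit by iteratively reweighted least squares (statsmodels binomial GLM)
    and Newton-polished to a small gradient norm; the odds ratio per unit
    is ``exp(beta1)`` with a 95% Wald interval.  Complete separation is
    reported through ``converged=False`` rather than an exception.
    """
    x = np.asarray(scores, dtype=float)
    y = _as_binary(outcome).astype(float)
    if x.shape != y.shape:
        raise ValueError("scores and outcome must have equal length")
    _require_both_classes(y.astype(bool))

    X = sm.add_constant(x)
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200, tol=1e-10)
        separation = any(
            issubclass(w.category, PerfectSeparationWarning) for w in caught
        )
    beta, cov, polished = _logistic_newton_polish(x, y, np.asarray(res.params))
    converged = bool(res.converged) and polished and not separation
    if not np.all(np.isfinite(beta)) or abs(beta[1]) > 30:
        converged = False

    se = float(np.sqrt(cov[1, 1])) if np.isfinite(cov[1, 1]) else float("nan")
    beta0, beta1 = float(beta[0]), float(beta[1])
    z = beta1 / se if se > 0 else float("nan")
    with np.errstate(over="ignore"):
        or_unit = float(np.exp(beta1))
        lo = float(np.exp(beta1 - 1.959963984540054 * se)) if se > 0 else float("nan")
        hi = float(np.exp(beta1 + 1.959963984540054 * se)) if se > 0 else float("nan")
    return LogisticFit(
        beta0=beta0,
        beta1=beta1,
        se_beta1=se,
        or_per_unit=or_unit,
        ci_low=lo,
        ci_high=hi,
        wald_p=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan"),
        converged=converged,
        n=x.size,
    )


# ---------------------------------------------------------------------------
# rank-sum comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class GroupComparison:
    """Score distributions in two outcome groups plus a rank-sum p-value."""

    group_a: GroupSummary
    group_b: GroupSummary
    rank_sum_p: float
    exact: bool


def _summarise(x: np.ndarray) -> GroupSummary:
    return GroupSummary(
        n=x.size,
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        median=float(np.median(x)),
        q1=float(np.percentile(x, 25)),
        q3=float(np.percentile(x, 75)),
    )


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive permutation p for the rank-sum statistic (midranks).

    Two-sided p is twice the smaller inclusive tail, capped at 1.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = a.size
    observed = ranks[:n_a].sum()
    sums = np.array(
        [ranks[list(idx)].sum() for idx in combinations(range(pooled.size), n_a)]
    )
    eps = 1e-9
    p_low = np.mean(sums <= observed + eps)
    p_high = np.mean(sums >= observed - eps)
    return float(min(1.0, 2 * min(p_low, p_high)))


def wilcoxon_rank_sum(scores_a, scores_b, exact_limit: int = 7) -> GroupComparison:
    """Compare score distributions between two groups.

    Uses exhaustive permutation enumeration when both groups have at most
    ``exact_limit`` observations (integer scores produce heavy ties, where
    the normal approximation is weakest), otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if max(a.size, b.size) <= exact_limit:
        p = _exact_rank_sum_p(a, b)
        exact = True
    else:
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
        exact = False
    return GroupComparison(
        group_a=_summarise(a), group_b=_summarise(b), rank_sum_p=p, exact=exact
    )


# ---------------------------------------------------------------------------
# ROC / AUC (DeLong)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCResult:
    """ROC curve with trapezoidal AUC and DeLong 95% interval.

    ``thresholds`` are descending; a point is generated for each rule
    "positive iff score >= threshold".  Sentinels above the maximum and
    below the minimum observed score pin the curve to (0,0) and (1,1).
    """

    thresholds: tuple[float, ...]
    sens: tuple[float, ...]
    one_minus_spec: tuple[float, ...]
    auc: float
    auc_se: float
    auc_ci_low: float
    auc_ci_high: float


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """AUC and DeLong structural components (placement values)."""
    pos = scores[y]
    neg = scores[~y]
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0) + 0.5 * (diff == 0)
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def roc_auc(scores, outcome) -> ROCResult:
    """ROC curve, trapezoidal AUC, and DeLong 95% CI."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(outcome)
    if s.shape != y.shape:
        raise ValueError("scores and outcome must have equal length")
    _require_both_classes(y)

    uniq = np.unique(s)[::-1]
    thresholds = np.concatenate([[uniq[0] + 1], uniq, [uniq[-1] - 1]])
    pos, neg = s[y], s[~y]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])

    # thresholds are descending, so (fpr, sens) is ascending from (0,0)
    # to (1,1); trapezoidal integration gives the AUC (equal to the
    # Mann-Whitney statistic with ties counted 1/2)
    auc = float(np.trapezoid(sens, fpr))
    _, v10, v01 = _delong_components(s, y)
    m, n = pos.size, neg.size
    var = 0.0
    if m > 1:
        var += float(np.var(v10, ddof=1)) / m
    if n > 1:
        var += float(np.var(v01, ddof=1)) / n
    se = math.sqrt(var)
    z = 1.959963984540054
    return ROCResult(
        thresholds=tuple(thresholds),
        sens=tuple(sens),
        one_minus_spec=tuple(fpr),
        auc=auc,
        auc_se=se,
        auc_ci_low=max(0.0, auc - z * se),
        auc_ci_high=min(1.0, auc + z * se),
    )


def compare_auc_paired(scores_1, scores_2, outcome) -> float:
    """Two-sided DeLong test for equal AUCs of two paired scores.

    Both score vectors must refer to the same subjects and outcome.  An
    identically-zero AUC difference returns p = 1.
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    y = _as_binary(outcome)
    if not (s1.shape == s2.shape == y.shape):
        raise ValueError("scores and outcome must have equal length")
    _require_both_classes(y)

    auc1, v10_1, v01_1 = _delong_components(s1, y)
    auc2, v10_2, v01_2 = _delong_components(s2, y)
    m, n = v10_1.size, v01_1.size
    var = 0.0
    if m > 1:
        cov10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
        var += (cov10[0, 0] + cov10[1, 1] - 2 * cov10[0, 1]) / m
    if n > 1:
        cov01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
        var += (cov01[0, 0] + cov01[1, 1] - 2 * cov01[0, 1]) / n
    diff = auc1 - auc2
    if var <= 1e-16:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / math.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# cutoff tables and 2x2 effect measures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CutoffEvaluation:
    """Classification and effect statistics when "score >= cutoff" flags risk.

    Percentages (sensitivity through npv, rd) are on the 0-100 scale at full
    precision.  ``rr``/``nnh`` are ``None`` when undefined (no events below
    the cutoff, or a non-positive risk difference); ``nnh_whole`` is the
    NNH rounded up to a whole person.
    """

    cutoff: float | None
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    correctly_classified: float
    ppv: float | None
    npv: float | None
    rd: float | None = None
    rr: float | None = None
    rr_ci_low: float | None = None
    rr_ci_high: float | None = None
    rr_defined: bool = False
    nnh: float | None = None
    nnh_whole: int | None = None
    nnh_defined: bool = False


def two_by_two_stats(
    n_below: int,
    events_below: int,
    n_above: int,
    events_above: int,
    cutoff: float | None = None,
) -> CutoffEvaluation:
    """Effect measures for a dichotomised cohort (below vs at-or-above).

    Risk difference is in percentage points; the risk-ratio interval is a
    log-scale Wald interval, asymptotically matching binomial-GLM
    inference; NNH = 100 / RD%, flagged undefined when RD <= 0.
    """
    for label, n, e in (("below", n_below, events_below), ("above", n_above, events_above)):
        if n <= 0:
            raise ValueError(f"group '{label}' must be nonempty")
        if not 0 <= e <= n:
            raise ValueError(f"events in group '{label}' must lie in [0, n]")

    tp, fn = events_above, events_below
    fp, tn = n_above - events_above, n_below - events_below
    total = n_below + n_above
    risk_below = events_below / n_below
    risk_above = events_above / n_above

    rd = 100.0 * (risk_above - risk_below)
    rr = rr_lo = rr_hi = None
    rr_defined = events_below > 0
    if rr_defined:
        rr = risk_above / risk_below
        if events_above > 0:
            se_log = math.sqrt(
                1 / events_above - 1 / n_above + 1 / events_below - 1 / n_below
            )
            z = 1.959963984540054
            rr_lo = rr * math.exp(-z * se_log)
            rr_hi = rr * math.exp(z * se_log)
        else:
            rr_lo, rr_hi = 0.0, float("nan")

    nnh = nnh_whole = None
    nnh_defined = rd > 0
    if nnh_defined:
        nnh = 100.0 / rd
        nnh_whole = math.ceil(nnh - 1e-12)

    pos_total = tp + fn
    neg_total = fp + tn
    return CutoffEvaluation(
        cutoff=cutoff,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=100.0 * tp / pos_total if pos_total else float("nan"),
        specificity=100.0 * tn / neg_total if neg_total else float("nan"),
        correctly_classified=100.0 * (tp + tn) / total,
        ppv=100.0 * tp / n_above,
        npv=100.0 * tn / n_below,
        rd=rd,
        rr=rr,
        rr_ci_low=rr_lo,
        rr_ci_high=rr_hi,
        rr_defined=rr_defined,
        nnh=nnh,
        nnh_whole=nnh_whole,
        nnh_defined=nnh_defined,
    )


def cutoff_table(scores, outcome, cutoffs=None) -> list[CutoffEvaluation]:
    """One :class:`CutoffEvaluation` per cutoff, ascending.

    Defaults to every observed score value.  At the minimal observed cutoff
    the below group is empty: sensitivity is 100%, specificity 0%, and the
    2x2 effect measures are undefined.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(outcome)
    if s.shape != y.shape:
        raise ValueError("scores and outcome must have equal length")
    _require_both_classes(y)
    if cutoffs is None:
        cutoffs = np.unique(s)

    rows = []
    total = s.size
    n_pos = int(y.sum())
    for c in cutoffs:
        above = s >= c
        n_above = int(above.sum())
        n_below = total - n_above
        ea = int(y[above].sum())
        eb = n_pos - ea
        if n_below == 0 or n_above == 0:
            tp, fn = ea, eb
            fp, tn = n_above - ea, n_below - eb
            rows.append(
                CutoffEvaluation(
                    cutoff=float(c),
                    tp=tp,
                    fp=fp,
                    tn=tn,
                    fn=fn,
                    sensitivity=100.0 * tp / n_pos,
                    specificity=100.0 * tn / (total - n_pos),
                    correctly_classified=100.0 * (tp + tn) / total,
                    ppv=100.0 * tp / n_above if n_above else None,
                    npv=100.0 * tn / n_below if n_below else None,
                )
            )
        else:
            rows.append(two_by_two_stats(n_below, eb, n_above, ea, cutoff=float(c)))
    return rows


def cutoff_table_frame(rows: list[CutoffEvaluation], precision: int = 1) -> pd.DataFrame:
    """Report-style DataFrame with table-rounded percentages."""
    records = []
    for r in rows:
        records.append(
            {
                "cutoff": r.cutoff,
                "tp": r.tp,
                "fp": r.fp,
                "tn": r.tn,
                "fn": r.fn,
                "sensitivity_pct": round_percent(r.sensitivity, precision),
                "specificity_pct": round_percent(r.specificity, precision),
                "correctly_classified_pct": round_percent(
                    r.correctly_classified, precision
                ),
                "ppv_pct": round_percent(r.ppv, precision),
                "npv_pct": round_percent(r.npv, precision),
                "rd_pct": round_percent(r.rd, precision),
                "rr": round_percent(r.rr, precision),
                "rr_ci_low": round_percent(r.rr_ci_low, precision),
                "rr_ci_high": round_percent(r.rr_ci_high, precision),
                "nnh": round_percent(r.nnh, precision),
                "nnh_whole": r.nnh_whole,
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# power and frequencies
# ---------------------------------------------------------------------------


def power_two_proportions(
    p1: float, p2: float, n1: int, n2: int, alpha: float = 0.05
) -> float:
    """Two-sided normal-approximation power for two independent proportions.

    Uses the pooled-variance z-test criterion under the null and the
    unpooled variance under the alternative (the classical post-hoc power
    formula).  When ``p1 == p2`` the power equals ``alpha``.
    """
    for p in (p1, p2):
        if not 0 < p < 1:
            raise ValueError("proportions must lie strictly in (0, 1)")
    if min(n1, n2) < 2:
        raise ValueError("group sizes must be at least 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")

    z_a = stats.norm.ppf(1 - alpha / 2)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    se0 = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    se1 = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    d = p1 - p2
    power = stats.norm.cdf((d - z_a * se0) / se1) + stats.norm.cdf(
        (-d - z_a * se0) / se1
    )
    return float(power)


def cumulative_frequency(scores) -> pd.DataFrame:
    """Per-score counts, percentages, and cumulative percentages.

    Percentages sum to 100 and the cumulative column is non-decreasing,
    ending at 100.
    """
    s = np.asarray(scores)
    if s.size == 0:
        raise ValueError("scores must be nonempty")
    values, counts = np.unique(s, return_counts=True)
    pct = 100.0 * counts / s.size
    return pd.DataFrame(
        {
            "score": values,
            "count": counts,
            "percent": pct,
            "cumulative_percent": np.cumsum(pct),
        }
    )
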