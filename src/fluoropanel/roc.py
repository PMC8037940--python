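"""ROC analysis for discrete allele-count scores.

The AUC is the tie-corrected pair-concordance probability (Mann-Whitney
convention): the probability that a random case outscores a random control,
with ties counted half. Because panel scores are small integers, ties are
the norm, and all routines here use the half-credit convention throughout;
the empirical ROC curve has a point at every distinct observed score and
its trapezoidal area equals the Mann-Whitney AUC.

Two panels genotyped on the same patients yield *correlated* AUCs, so the
comparison resamples whole patients with replacement (scores for both
panels drawn jointly), recomputes the AUC difference each iterate, and
refers the full-sample difference over the bootstrap standard error to a
normal distribution (Wald test). Normal-approximation confidence intervals
from the bootstrap SE are primary; raw percentile intervals are also
reported.

Power for detecting AUC != 0.5 uses the Hanley-McNeil binormal-variance
approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, rankdata

__all__ = [
    "RocResult",
    "RocComparison",
    "PowerResult",
    "mann_whitney_auc",
    "roc_curve_points",
    "roc_auc",
    "compare_roc_bootstrap",
    "delong_test",
    "roc_power",
    "min_detectable_auc",
]


def _as_arrays(score, outcome) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(score, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("score and outcome must have equal length")
    if not y.any():
        raise ValueError("no positive outcomes (case class empty)")
    if y.all():
        raise ValueError("no negative outcomes (control class empty)")
    return s, y


def mann_whitney_auc(score, outcome) -> float:
    """Tie-corrected AUC via midranks.

    AUC = [#(case > control) + 0.5 * #(ties)] / (n_case * n_control),
    computed as (R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg) with average
    ranks.
    """
    s, y = _as_arrays(score, outcome)
    ranks = rankdata(s)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    r_pos = ranks[y].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve_points(score, outcome) -> np.ndarray:
    """Empirical ROC curve: (1 - specificity, sensitivity) pairs.

    One threshold per distinct observed score (test positive when
    score >= threshold), thresholds descending, with the trivial (0, 0)
    and (1, 1) endpoints included. The trapezoidal area under the returned
    polyline equals :func:`mann_whitney_auc`.
    """
    s, y = _as_arrays(score, outcome)
    thresholds = np.unique(s)[::-1]
    n_pos = y.sum()
    n_neg = y.size - n_pos
    points = [(0.0, 0.0)]
    for t in thresholds:
        positive = s >= t
        tpr = (positive & y).sum() / n_pos
        fpr = (positive & ~y).sum() / n_neg
        points.append((float(fpr), float(tpr)))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return np.asarray(points)


def _delong_variance(s: np.ndarray, y: np.ndarray) -> float:
    """DeLong structural-component variance of a single AUC."""
    pos, neg = s[y], s[~y]
    # placement of each case among controls and vice versa
    v10 = np.mean(pos[:, None] > neg[None, :], axis=1) + 0.5 * np.mean(
        pos[:, None] == neg[None, :], axis=1
    )
    v01 = np.mean(pos[:, None] > neg[None, :], axis=0) + 0.5 * np.mean(
        pos[:, None] == neg[None, :], axis=0
    )
    return float(np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg))


@dataclass(frozen=True)
class RocResult:
    """AUC with a DeLong-variance normal CI and the empirical curve."""

    model_id: str | None
    auc: float
    ci: tuple[float, float]
    curve_points: np.ndarray
    n_pos: int
    n_neg: int


def roc_auc(score, outcome, model_id: str | None = None, ci_level: float = 0.95) -> RocResult:
    """AUC, confidence interval and ROC curve for one score."""
    s, y = _as_arrays(score, outcome)
    auc = mann_whitney_auc(s, y)
    se = math.sqrt(_delong_variance(s, y)) if y.sum() > 1 and (~y).sum() > 1 else math.nan
    z = norm.ppf(0.5 + ci_level / 2)
    ci = (
        (max(0.0, auc - z * se), min(1.0, auc + z * se))
        if math.isfinite(se)
        else (math.nan, math.nan)
    )
    return RocResult(
        model_id=model_id,
        auc=auc,
        ci=ci,
        curve_points=roc_curve_points(s, y),
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
    )


def _auc_from_ranks(s: np.ndarray, y: np.ndarray) -> float:
    ranks = rankdata(s)
    n_pos = y.sum()
    n_neg = y.size - n_pos
    return (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


@dataclass(frozen=True)
class RocComparison:
    """Paired-bootstrap comparison of two panel AUCs on the same patients."""

    model_a: str
    model_b: str
    auc_a: float
    auc_b: float
    delta: float  # auc_b - auc_a, full sample
    se: float
    ci: tuple[float, float]  # normal-approximation (primary)
    ci_percentile: tuple[float, float]
    wald_p: float
    n_boot: int
    seed: int | None
    n_samples: int
    n_redraws: int  # degenerate resamples (one outcome class empty) redrawn


def compare_roc_bootstrap(
    score_a,
    score_b,
    outcome,
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
    stratified: bool = False,
    model_a: str = "model_a",
    model_b: str = "model_b",
) -> RocComparison:
    """Compare two correlated AUCs by paired patient-level bootstrap.

    Patients are resampled with replacement (both scores jointly) ``n_boot``
    times; the SE of the AUC difference is the standard deviation of the
    bootstrap differences, the CI is the normal approximation around the
    full-sample difference, and the Wald p-value is the two-sided normal
    tail of delta/SE. Resamples that lose an outcome class entirely are
    redrawn (``n_redraws`` reports how many); ``stratified=True`` instead
    resamples cases and controls separately, which cannot degenerate and is
    advisable for very rare outcomes.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    sa = np.asarray(score_a, dtype=float)
    sb = np.asarray(score_b, dtype=float)
    _, y = _as_arrays(sa, outcome)
    if sb.shape != sa.shape:
        raise ValueError("scores must be defined on an identical sample set")
    n = y.size
    auc_a = _auc_from_ranks(sa, y)
    auc_b = _auc_from_ranks(sb, y)
    delta = auc_b - auc_a
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    deltas = np.empty(n_boot)
    n_redraws = 0
    for b in range(n_boot):
        if stratified:
            idx = np.concatenate(
                [
                    rng.choice(pos_idx, size=pos_idx.size, replace=True),
                    rng.choice(neg_idx, size=neg_idx.size, replace=True),
                ]
            )
        else:
            idx = rng.integers(0, n, size=n)
            while y[idx].all() or not y[idx].any():
                n_redraws += 1
                idx = rng.integers(0, n, size=n)
        yb = y[idx]
        deltas[b] = _auc_from_ranks(sb[idx], yb) - _auc_from_ranks(sa[idx], yb)
    se = float(np.std(deltas, ddof=1))
    z = norm.ppf(0.5 + ci_level / 2)
    alpha = 1.0 - ci_level
    if se == 0.0:
        wald_p = 1.0 if delta == 0.0 else 0.0
        ci = (delta, delta)
    else:
        wald_p = float(2.0 * norm.sf(abs(delta) / se))
        ci = (delta - z * se, delta + z * se)
    ci_pct = tuple(np.quantile(deltas, [alpha / 2, 1 - alpha / 2]))
    return RocComparison(
        model_a=model_a,
        model_b=model_b,
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        delta=float(delta),
        se=se,
        ci=ci,
        ci_percentile=(float(ci_pct[0]), float(ci_pct[1])),
        wald_p=wald_p,
        n_boot=n_boot,
        seed=seed,
        n_samples=n,
        n_redraws=n_redraws,
    )


def delong_test(score_a, score_b, outcome) -> tuple[float, float]:
    """Analytic DeLong paired test: returns (delta AUC, two-sided p).

    Cross-check utility for the bootstrap comparison; the bootstrap is the
    primary contract.
    """
    sa = np.asarray(score_a, dtype=float)
    sb = np.asarray(score_b, dtype=float)
    _, y = _as_arrays(sa, outcome)
    pos_a, neg_a = sa[y], sa[~y]
    pos_b, neg_b = sb[y], sb[~y]

    def placements(pos, neg):
        gt = pos[:, None] > neg[None, :]
        eq = pos[:, None] == neg[None, :]
        psi = gt + 0.5 * eq
        return psi.mean(axis=1), psi.mean(axis=0), psi.mean()

    v10_a, v01_a, auc_a = placements(pos_a, neg_a)
    v10_b, v01_b, auc_b = placements(pos_b, neg_b)
    m, n = len(pos_a), len(neg_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (
        s10[0, 0] / m + s01[0, 0] / n
        + s10[1, 1] / m + s01[1, 1] / n
        - 2 * (s10[0, 1] / m + s01[0, 1] / n)
    )
    delta = auc_b - auc_a
    if var <= 0:
        return float(delta), 1.0 if delta == 0 else 0.0
    z = delta / math.sqrt(var)
    return float(delta), float(2.0 * norm.sf(abs(z)))


# -- power ----------------------------------------------------------------


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    return math.sqrt(var)


@dataclass(frozen=True)
class PowerResult:
    auc_alt: float
    n_pos: int
    n_neg: int
    alpha: float
    power: float


def roc_power(
    auc_alt: float, n_pos: int, n_neg: int, alpha: float = 0.05
) -> PowerResult:
    """Power of the two-sided test of AUC = 0.5 against ``auc_alt``.

    Uses the Hanley-McNeil binormal-variance approximation for the AUC
    standard error under both hypotheses. Power is monotone in ``auc_alt``
    and in the class sizes, and tends to ``alpha`` as ``auc_alt`` tends to
    0.5 from above.
    """
    if not 0.5 < auc_alt < 1.0:
        raise ValueError("auc_alt must be in (0.5, 1)")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class sizes must be >= 1")
    se0 = _hanley_mcneil_se(0.5, n_pos, n_neg)
    se1 = _hanley_mcneil_se(auc_alt, n_pos, n_neg)
    z = norm.ppf(1.0 - alpha / 2.0)
    shift = auc_alt - 0.5
    power = norm.sf((z * se0 - shift) / se1) + norm.cdf((-z * se0 - shift) / se1)
    return PowerResult(auc_alt, n_pos, n_neg, alpha, float(power))


def min_detectable_auc(
    n_pos: int, n_neg: int, power: float = 0.80, alpha: float = 0.05
) -> float:
    """Smallest alternative AUC detectable at the target power."""
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")

    def gap(a: float) -> float:
        return roc_power(a, n_pos, n_neg, alpha).power - power

    lo, hi = 0.5 + 1e-9, 1.0 - 1e-12
    if gap(hi) < 0:
        raise ValueError("target power unattainable even at AUC ~ 1")
    return float(brentq(gap, lo, hi, xtol=1e-10))


def comparison_table(comparisons: list[RocComparison]) -> pd.DataFrame:
    """Tabular layout of pairwise comparisons (one row per comparison)."""
    return pd.DataFrame(
        [
            {
                "model_a": c.model_a,
                "model_b": c.model_b,
                "auc_a": c.auc_a,
                "auc_b": c.auc_b,
                "delta_auc": c.delta,
                "ci_low": c.ci[0],
                "ci_high": c.ci[1],
                "wald_p": c.wald_p,
                "n": c.n_samples,
                "n_boot": c.n_boot,
                "seed": c.seed,
            }
            for c in comparisons
        ]
    )
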