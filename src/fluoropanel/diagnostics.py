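"""Diagnostic accuracy of a binary panel test against graded toxicity.

Toxicity is recorded per patient and endpoint as an NCI CTCAE grade (0-4;
treatment-related death is carried as a separate binary endpoint). Graded
outcomes are collapsed to binary with named codings:

* ``g012_v_34`` — positive when grade >= 3 (serious event);
* ``g0123_v_4`` — positive when grade = 4 (life-threatening event);
* ``g012_v_3``  — grades 0-2 versus grade 3, used for mucositis/stomatitis
  where grade 4 events are not expected (implemented as grade >= 3).

From a 2x2 confusion table the module derives sensitivity, specificity,
predictive values and likelihood ratios, with Wilson score intervals for
the proportions and log-method intervals for the likelihood ratios. A
"good" rule-in test has LR+ > 10 and LR- < 1 (Simundic thresholds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "Endpoint",
    "BinaryCoding",
    "ConfusionTable",
    "DiagnosticMetrics",
    "binarize",
    "derive_haematological",
    "derive_global",
    "confusion",
    "diagnostic_metrics",
    "lr_plus",
    "lr_minus",
    "grade_good_test",
    "GLOBAL_COMPONENT_ENDPOINTS",
]


class Endpoint(str, Enum):
    DIARRHOEA = "diarrhoea"
    VOMITING = "vomiting"
    HFS = "hfs"
    NEUTROPENIA = "neutropenia"
    THROMBOCYTOPENIA = "thrombocytopenia"
    HAEMATOLOGICAL = "haematological"
    MUCOSITIS_STOMATITIS = "mucositis_stomatitis"
    GLOBAL = "global"
    DEATH = "death"


#: endpoints contributing to the derived global-toxicity variable
GLOBAL_COMPONENT_ENDPOINTS = (
    Endpoint.DIARRHOEA,
    Endpoint.VOMITING,
    Endpoint.HFS,
    Endpoint.NEUTROPENIA,
    Endpoint.THROMBOCYTOPENIA,
    Endpoint.MUCOSITIS_STOMATITIS,
)


class BinaryCoding(str, Enum):
    G012_V_34 = "g012_v_34"  # grade >= 3
    G0123_V_4 = "g0123_v_4"  # grade = 4
    G012_V_3 = "g012_v_3"    # grades 0-2 vs 3 (mucositis/stomatitis)
    BINARY = "binary"        # already 0/1 (death)


_CODING_PREDICATES = {
    BinaryCoding.G012_V_34: lambda g: g >= 3,
    BinaryCoding.G0123_V_4: lambda g: g == 4,
    BinaryCoding.G012_V_3: lambda g: g >= 3,
    BinaryCoding.BINARY: lambda g: g >= 1,
}


def _endpoint_grades(tox: pd.DataFrame, endpoint: Endpoint | str) -> pd.Series:
    endpoint = Endpoint(endpoint)
    sub = tox[tox["endpoint"] == endpoint.value]
    if sub["sample_id"].duplicated().any():
        dup = sub.loc[sub["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(
            f"duplicate grade for sample {dup!r}, endpoint {endpoint.value!r}"
        )
    return sub.set_index("sample_id")["grade"].astype(int)


def binarize(
    tox: pd.DataFrame, endpoint: Endpoint | str, coding: BinaryCoding | str
) -> pd.Series:
    """Binary outcome per sample for one endpoint and coding.

    ``tox`` is a long-form table with columns sample_id, endpoint, grade.
    Samples with no grade recorded for the endpoint are simply absent from
    the returned Series (they are excluded from that endpoint's analysis).
    """
    coding = BinaryCoding(coding)
    grades = _endpoint_grades(tox, endpoint)
    predicate = _CODING_PREDICATES[coding]
    return grades.map(predicate).astype(bool)


def derive_haematological(tox: pd.DataFrame) -> pd.DataFrame:
    """Append the combined haematological endpoint.

    Haematological grade = max(neutropenia, thrombocytopenia) per sample,
    over samples with at least one of the two recorded.
    """
    neut = _endpoint_grades(tox, Endpoint.NEUTROPENIA)
    thromb = _endpoint_grades(tox, Endpoint.THROMBOCYTOPENIA)
    combined = pd.concat([neut, thromb], axis=1).max(axis=1).astype(int)
    add = pd.DataFrame(
        {
            "sample_id": combined.index,
            "endpoint": Endpoint.HAEMATOLOGICAL.value,
            "grade": combined.to_numpy(),
        }
    )
    keep = tox[tox["endpoint"] != Endpoint.HAEMATOLOGICAL.value]
    return pd.concat([keep, add], ignore_index=True)


def derive_global(tox: pd.DataFrame) -> pd.DataFrame:
    """Append the derived global-toxicity endpoint.

    Global grade = max grade over the six contributing endpoints; a sample
    enters the global analysis when at least one contributing endpoint is
    recorded (missing endpoints are not imputed as zero for samples with no
    toxicity data at all).
    """
    components = [e.value for e in GLOBAL_COMPONENT_ENDPOINTS]
    sub = tox[tox["endpoint"].isin(components)]
    combined = (
        sub.groupby("sample_id")["grade"].max().astype(int)
        if len(sub)
        else pd.Series(dtype=int)
    )
    add = pd.DataFrame(
        {
            "sample_id": combined.index,
            "endpoint": Endpoint.GLOBAL.value,
            "grade": combined.to_numpy(),
        }
    )
    keep = tox[tox["endpoint"] != Endpoint.GLOBAL.value]
    return pd.concat([keep, add], ignore_index=True)


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(test_positive: pd.Series, outcome_positive: pd.Series) -> ConfusionTable:
    """2x2 table over the samples present in both inputs."""
    common = test_positive.index.intersection(outcome_positive.index)
    if len(common) == 0:
        raise ValueError("no samples shared between test and outcome")
    t = test_positive.loc[common].astype(bool)
    o = outcome_positive.loc[common].astype(bool)
    return ConfusionTable(
        tp=int((t & o).sum()),
        fp=int((t & ~o).sum()),
        tn=int((~t & ~o).sum()),
        fn=int((~t & o).sum()),
    )


def lr_plus(sensitivity: float, specificity: float) -> float:
    """Likelihood ratio of a positive test, sens / (1 - spec)."""
    denominator = 1.0 - specificity
    if denominator == 0.0:
        return math.inf if sensitivity > 0 else math.nan
    return sensitivity / denominator


def lr_minus(sensitivity: float, specificity: float) -> float:
    """Likelihood ratio of a negative test, (1 - sens) / spec."""
    if specificity == 0.0:
        return math.inf if sensitivity < 1 else math.nan
    return (1.0 - sensitivity) / specificity


@dataclass(frozen=True)
class DiagnosticMetrics:
    """2x2-derived accuracy measures with confidence intervals.

    Proportion CIs are Wilson score intervals; likelihood-ratio CIs use the
    standard log method. Ratios may be ``inf`` and undefined quantities
    (e.g. PPV with no positive tests) are ``nan``.
    """

    table: ConfusionTable
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_plus: float
    lr_minus: float
    ci_level: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    lr_plus_ci: tuple[float, float]
    lr_minus_ci: tuple[float, float]


def _proportion(k: int, n: int, alpha: float) -> tuple[float, tuple[float, float]]:
    if n == 0:
        return math.nan, (math.nan, math.nan)
    low, high = proportion_confint(k, n, alpha=alpha, method="wilson")
    return k / n, (float(low), float(high))


def _lr_ci(
    value: float, num_k: int, num_n: int, den_k: int, den_n: int, alpha: float
) -> tuple[float, float]:
    """Log-method CI for a ratio of two proportions (likelihood ratio)."""
    from scipy.stats import norm

    if not math.isfinite(value) or value <= 0 or num_k == 0 or den_k == 0:
        return (math.nan, math.nan)
    se = math.sqrt(1 / num_k - 1 / num_n + 1 / den_k - 1 / den_n)
    z = norm.ppf(1 - alpha / 2)
    return (value * math.exp(-z * se), value * math.exp(z * se))


def diagnostic_metrics(ct: ConfusionTable, ci_level: float = 0.95) -> DiagnosticMetrics:
    """All accuracy measures from a 2x2 table.

    Requires at least one case and one control (otherwise sensitivity or
    specificity is undefined); an all-zero table is an error.
    """
    if ct.n == 0:
        raise ValueError("empty confusion table")
    alpha = 1.0 - ci_level
    n_pos, n_neg = ct.tp + ct.fn, ct.tn + ct.fp
    sens, sens_ci = _proportion(ct.tp, n_pos, alpha)
    spec, spec_ci = _proportion(ct.tn, n_neg, alpha)
    ppv, ppv_ci = _proportion(ct.tp, ct.tp + ct.fp, alpha)
    npv, npv_ci = _proportion(ct.tn, ct.tn + ct.fn, alpha)
    lrp = lr_plus(sens, spec) if n_pos and n_neg else math.nan
    lrm = lr_minus(sens, spec) if n_pos and n_neg else math.nan
    return DiagnosticMetrics(
        table=ct,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_plus=lrp,
        lr_minus=lrm,
        ci_level=ci_level,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
        ppv_ci=ppv_ci,
        npv_ci=npv_ci,
        lr_plus_ci=_lr_ci(lrp, ct.tp, n_pos, ct.fp, n_neg, alpha),
        lr_minus_ci=_lr_ci(lrm, ct.fn, n_pos, ct.tn, n_neg, alpha),
    )


def grade_good_test(metrics: DiagnosticMetrics | tuple[float, float]) -> str:
    """'good' when LR+ > 10 and LR- < 1 (Simundic rule-in thresholds)."""
    if isinstance(metrics, DiagnosticMetrics):
        lrp, lrm = metrics.lr_plus, metrics.lr_minus
    else:
        lrp, lrm = metrics
    return "good" if lrp > 10 and lrm < 1 else "not_good"
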