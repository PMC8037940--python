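"""End-to-end panel evaluation: QC -> scoring -> diagnostics -> comparative
ROC -> risk-tier report.

:func:`run_analysis` reproduces the structure of a panel-evaluation report
from any cohort (real or synthetic): a per-variant QC table, per-model
diagnostic metrics for each endpoint/coding, a pairwise AUC-comparison
table (baseline model versus each comparator, paired bootstrap), the
per-sample risk-tier table with stratum counts, and a run manifest. Each
model comparison uses the intersection of samples fully genotyped for the
union of the two models' variants, so different comparisons may have
different n.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__ as _pkg_version
from .catalog import Catalog
from .diagnostics import (
    BinaryCoding,
    Endpoint,
    binarize,
    confusion,
    derive_global,
    derive_haematological,
    diagnostic_metrics,
    grade_good_test,
)
from .genotypes import GenotypeMatrix, variant_qc
from .roc import compare_roc_bootstrap, comparison_table, mann_whitney_auc
from .scoring import (
    DEFAULT_HFS_VARIANTS,
    activity_score,
    allele_sum_score,
    classify_risk,
    tier_counts,
)

__all__ = [
    "AnalysisPlan",
    "AnalysisReport",
    "run_analysis",
    "high_risk_outcome_summary",
    "DEFAULT_ENDPOINT_CODINGS",
]

logger = logging.getLogger("fluoropanel.pipeline")

#: the eight standard endpoint/coding rows of a panel-evaluation report
DEFAULT_ENDPOINT_CODINGS: tuple[tuple[str, str], ...] = (
    (Endpoint.DEATH.value, BinaryCoding.BINARY.value),
    (Endpoint.HAEMATOLOGICAL.value, BinaryCoding.G0123_V_4.value),
    (Endpoint.HAEMATOLOGICAL.value, BinaryCoding.G012_V_34.value),
    (Endpoint.DIARRHOEA.value, BinaryCoding.G0123_V_4.value),
    (Endpoint.DIARRHOEA.value, BinaryCoding.G012_V_34.value),
    (Endpoint.MUCOSITIS_STOMATITIS.value, BinaryCoding.G012_V_3.value),
    (Endpoint.GLOBAL.value, BinaryCoding.G012_V_34.value),
    (Endpoint.HFS.value, BinaryCoding.G012_V_34.value),
)


@dataclass(frozen=True)
class AnalysisPlan:
    """What to compute and how."""

    baseline_model: str = "model1"
    comparison_models: tuple[str, ...] = ("model2",)
    endpoint_codings: tuple[tuple[str, str], ...] = DEFAULT_ENDPOINT_CODINGS
    n_boot: int = 1000
    seed: int = 0
    ci_level: float = 0.95
    hfs_variants: tuple[str, ...] = DEFAULT_HFS_VARIANTS

    def validate(self, catalog: Catalog) -> None:
        for model_id in (self.baseline_model, *self.comparison_models):
            catalog.model(model_id)  # raises KeyError on unknown model
        for endpoint, coding in self.endpoint_codings:
            Endpoint(endpoint)
            BinaryCoding(coding)


@dataclass
class AnalysisReport:
    """Report bundle; every table is re-derivable from the inputs."""

    qc: pd.DataFrame
    metrics: pd.DataFrame
    comparisons: pd.DataFrame
    tiers: pd.DataFrame
    tier_counts: dict[str, int]
    high_risk_summary: dict
    manifest: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
        self.metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        self.comparisons.to_csv(outdir / "roc_comparisons.tsv", sep="\t", index=False)
        self.tiers.to_csv(outdir / "risk_tiers.tsv", sep="\t")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(
                {
                    "tier_counts": self.tier_counts,
                    "high_risk_summary": self.high_risk_summary,
                    "manifest": self.manifest,
                },
                fh,
                indent=2,
            )


def _prepare_toxicity(toxicity: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "endpoint", "grade"}
    if not required.issubset(toxicity.columns):
        raise ValueError(f"toxicity table must have columns {sorted(required)}")
    tox = toxicity.copy()
    tox["sample_id"] = tox["sample_id"].astype(str)
    endpoints = set(tox["endpoint"])
    if (
        Endpoint.NEUTROPENIA.value in endpoints
        and Endpoint.THROMBOCYTOPENIA.value in endpoints
    ):
        tox = derive_haematological(tox)
    tox = derive_global(tox)
    return tox


def _model_scores(matrix: GenotypeMatrix, catalog: Catalog, model_id: str):
    return allele_sum_score(matrix, catalog.model(model_id))


def run_analysis(
    plan: AnalysisPlan,
    genotypes: GenotypeMatrix,
    toxicity: pd.DataFrame,
    catalog: Catalog,
) -> AnalysisReport:
    """Run the full evaluation; see module docstring for the report layout."""
    plan.validate(catalog)
    tox = _prepare_toxicity(toxicity)
    logger.info(
        "inputs: %d samples x %d variants, %d toxicity rows",
        genotypes.n_samples,
        len(genotypes.variant_ids),
        len(tox),
    )

    qc = variant_qc(genotypes)
    logger.info("qc: %d variants, %d flagged", len(qc), int((qc["flags"] != "").sum()))

    # per-model diagnostic metrics on each endpoint/coding
    metric_rows = []
    model_ids = [plan.baseline_model, *plan.comparison_models]
    for model_id in model_ids:
        result = _model_scores(genotypes, catalog, model_id)
        test_positive = result.scores["positive"]
        for endpoint, coding in plan.endpoint_codings:
            outcome = binarize(tox, endpoint, coding)
            common = test_positive.index.intersection(outcome.index)
            if len(common) == 0 or outcome.loc[common].nunique() < 2:
                continue  # endpoint absent or degenerate in this cohort
            ct = confusion(test_positive, outcome)
            m = diagnostic_metrics(ct, plan.ci_level)
            metric_rows.append(
                {
                    "model_id": model_id,
                    "endpoint": endpoint,
                    "coding": coding,
                    "n": ct.n,
                    "tp": ct.tp,
                    "fp": ct.fp,
                    "tn": ct.tn,
                    "fn": ct.fn,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "ppv": m.ppv,
                    "npv": m.npv,
                    "lr_plus": m.lr_plus,
                    "lr_minus": m.lr_minus,
                    "good_test": grade_good_test(m),
                }
            )
    metrics = pd.DataFrame(metric_rows)
    logger.info("diagnostics: %d model x endpoint rows", len(metrics))

    # pairwise comparative ROC: baseline vs each comparator, per endpoint
    comparisons = []
    base_model = catalog.model(plan.baseline_model)
    for comp_id in plan.comparison_models:
        comp_model = catalog.model(comp_id)
        union_vids = list(
            dict.fromkeys([*base_model.variant_ids, *comp_model.variant_ids])
        )
        retained, excluded = genotypes.complete_cases(union_vids)
        if excluded:
            logger.info(
                "comparison %s vs %s: %d samples excluded (incomplete genotypes)",
                plan.baseline_model,
                comp_id,
                len(excluded),
            )
        score_a = allele_sum_score(retained, base_model).scores["score"]
        score_b = allele_sum_score(retained, comp_model).scores["score"]
        for endpoint, coding in plan.endpoint_codings:
            outcome = binarize(tox, endpoint, coding)
            common = score_a.index.intersection(outcome.index)
            y = outcome.loc[common]
            if len(common) == 0 or y.nunique() < 2:
                continue
            comparison = compare_roc_bootstrap(
                score_a.loc[common].to_numpy(),
                score_b.loc[common].to_numpy(),
                y.to_numpy(),
                n_boot=plan.n_boot,
                seed=plan.seed,
                ci_level=plan.ci_level,
                model_a=plan.baseline_model,
                model_b=comp_id,
            )
            row = comparison_table([comparison]).iloc[0].to_dict()
            row["endpoint"], row["coding"] = endpoint, coding
            comparisons.append(row)
    comparisons_df = pd.DataFrame(comparisons)
    logger.info("comparative ROC: %d comparisons", len(comparisons_df))

    # risk tiers
    activity = activity_score(genotypes, catalog)
    tiers = classify_risk(activity, genotypes, plan.hfs_variants)
    counts = tier_counts(tiers)
    summary = high_risk_outcome_summary(tiers, tox)
    logger.info("risk tiers: %s", counts)

    manifest = {
        "package_version": _pkg_version,
        "seed": plan.seed,
        "n_boot": plan.n_boot,
        "ci_level": plan.ci_level,
        "baseline_model": plan.baseline_model,
        "comparison_models": list(plan.comparison_models),
        "n_samples": genotypes.n_samples,
        "config_hash": _plan_hash(plan),
    }
    return AnalysisReport(
        qc=qc,
        metrics=metrics,
        comparisons=comparisons_df,
        tiers=tiers,
        tier_counts=counts,
        high_risk_summary=summary,
        manifest=manifest,
    )


def _plan_hash(plan: AnalysisPlan) -> str:
    blob = json.dumps(
        {
            "baseline_model": plan.baseline_model,
            "comparison_models": list(plan.comparison_models),
            "endpoint_codings": [list(ec) for ec in plan.endpoint_codings],
            "n_boot": plan.n_boot,
            "seed": plan.seed,
            "ci_level": plan.ci_level,
            "hfs_variants": list(plan.hfs_variants),
        },
        sort_keys=True,
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def high_risk_outcome_summary(
    tiers: pd.DataFrame,
    toxicity: pd.DataFrame,
    dose_modifications: pd.DataFrame | None = None,
) -> dict:
    """Outcomes of the patients flagged critical or high risk.

    Counts, among flagged patients, those with any grade 3/4 event across
    the six endpoints contributing to global toxicity, as a count and
    percentage. When a ``dose_modifications`` table is supplied (columns
    sample_id, withdrawal, dose_reduction, dose_delay; boolean), the
    fraction with a withdrawal or dose reduction/delay is reported too.
    """
    flagged = tiers[tiers["tier"].isin(["critical", "high"])].index
    if len(flagged) == 0:
        return {"n_flagged": 0, "note": "no critical/high risk samples"}
    tox = derive_global(toxicity)
    outcome = binarize(tox, Endpoint.GLOBAL, BinaryCoding.G012_V_34)
    flagged_outcomes = outcome.reindex(flagged).fillna(False)
    n_events = int(flagged_outcomes.sum())
    summary = {
        "n_flagged": int(len(flagged)),
        "n_grade34_event": n_events,
        "pct_grade34_event": round(100.0 * n_events / len(flagged), 1),
    }
    if dose_modifications is not None:
        dm = dose_modifications.set_index(
            dose_modifications["sample_id"].astype(str)
        )
        dm = dm.reindex(flagged)
        withdrew = dm["withdrawal"].fillna(False).astype(bool)
        modified = (
            dm[["dose_reduction", "dose_delay"]]
            .fillna(False)
            .astype(bool)
            .any(axis=1)
        )
        n_any = int((withdrew | modified).sum())
        summary.update(
            {
                "n_withdrawal": int(withdrew.sum()),
                "n_dose_modified": int((modified & ~withdrew).sum()),
                "n_withdrawal_or_modification": n_any,
                "pct_withdrawal_or_modification": round(
                    100.0 * n_any / len(flagged), 1
                ),
            }
        )
    return summary
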