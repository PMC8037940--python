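"""Risk scoring and four-tier risk classification.

Three layers:

* **Allele-sum scores** — for a panel model, each patient's score is the
  summed risk-allele dosage over the model's variants; the binary test is
  positive at or above the model's cut-point (default 1 risk allele).
* **DPD activity scores** — the diploid sum of the two least-active DPYD
  alleles attributed to the patient (normal allele 1.0, decreased function
  0.5, no function 0.0), giving scores in {0, 0.5, 1, 1.5, 2}. Common
  toxicity-risk SNPs never enter the activity score. Phase is unknown, so
  co-occurring deficiency alleles are conservatively assumed in trans and
  flagged as possible compound genotypes.
* **Risk tiers** — the clinician-facing classification:

  ========================  =================================
  activity score 0 or 0.5   critical (avoid 5-FU)
  activity score 1 or 1.5   high (50% dose reduction)
  2, >=1 HFS risk allele    standard, high risk of HFS
  2, no HFS risk allele     standard
  ========================  =================================

  where the HFS (hand-foot syndrome) risk alleles default to the
  ENOSF1/intergenic pair rs2612091 and rs12132152.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .catalog import Catalog, PanelModel
from .genotypes import GenotypeMatrix

__all__ = [
    "RiskTier",
    "ScoreResult",
    "allele_sum_score",
    "activity_score",
    "classify_risk",
    "tier_counts",
    "DEFAULT_HFS_VARIANTS",
    "TIER_RECOMMENDATIONS",
]

DEFAULT_HFS_VARIANTS = ("rs2612091", "rs12132152")


class RiskTier(str, Enum):
    CRITICAL = "critical"
    HIGH = "high"
    STANDARD_HIGH_HFS = "standard_high_hfs"
    STANDARD = "standard"


#: clinician-facing interpretation attached to reports
TIER_RECOMMENDATIONS = {
    RiskTier.CRITICAL: (
        "CRITICAL RISK - predicted DPD deficient (activity score 0 or 0.5): "
        "avoid use of 5-FU or 5-FU prodrug-based regimens."
    ),
    RiskTier.HIGH: (
        "HIGH RISK - partial DPD deficiency (activity score 1 or 1.5): "
        "dose modulation of 50% is recommended; consider dose titration "
        "guided by toxicity after the first 2 cycles."
    ),
    RiskTier.STANDARD_HIGH_HFS: (
        "STANDARD RISK, HIGH RISK OF HFS (activity score 2, >=1 HFS risk "
        "allele): no dose change indicated; advise on prevention and "
        "management of hand-foot syndrome."
    ),
    RiskTier.STANDARD: (
        "STANDARD RISK (activity score 2): no indication to change dose or "
        "therapy; use label-recommended dosage."
    ),
}


@dataclass
class ScoreResult:
    """Per-sample scores for one model plus the samples excluded as
    incompletely genotyped."""

    model_id: str
    scores: pd.DataFrame  # columns: score (int), positive (bool); index sample_id
    excluded_samples: list[str]


def allele_sum_score(matrix: GenotypeMatrix, model: PanelModel) -> ScoreResult:
    """Summed risk-allele count per sample for one panel model.

    Samples missing any genotype among the model's variants are excluded
    and reported in ``excluded_samples`` (only fully genotyped samples enter
    panel testing).
    """
    retained, excluded = matrix.complete_cases(list(model.variant_ids))
    sub = retained.dosages[list(model.variant_ids)]
    score = sub.sum(axis=1).astype(int)
    out = pd.DataFrame(
        {"score": score, "positive": score >= model.cutpoint},
        index=sub.index,
    )
    return ScoreResult(model.model_id, out, excluded)


def _sample_activity(
    dosages: pd.Series, activities: dict[str, float], order: list[str]
) -> tuple[float, list[tuple[str, int]], bool]:
    """Activity score for one sample.

    Collects every deficiency-allele copy (dosage-weighted), pads with
    normal alleles (activity 1.0) to two alleles, and sums the two
    least-active. Returns (score, contributing alleles, compound flag).
    Catalogue order breaks ties among equal-activity alleles.
    """
    copies: list[tuple[float, str]] = []
    contributing: list[tuple[str, int]] = []
    for vid in order:
        d = dosages.get(vid)
        n = 0 if d is None or np.isnan(d) else int(d)
        if n > 0:
            contributing.append((vid, n))
            copies.extend([(activities[vid], vid)] * n)
    copies.sort(key=lambda pair: (pair[0], order.index(pair[1])))
    two_least = [a for a, _ in copies[:2]]
    while len(two_least) < 2:
        two_least.append(1.0)
    return float(sum(two_least)), contributing, len(copies) > 2


def activity_score(matrix: GenotypeMatrix, catalog: Catalog) -> pd.DataFrame:
    """DPD activity score per sample.

    Returns a DataFrame indexed by sample with columns ``activity_score``,
    ``contributing_alleles`` (semicolon-joined ``variant_id x dosage``) and
    ``compound_warning`` (True when more than two deficiency-allele copies
    were observed — phase unknown, alleles assumed in trans). Missing
    genotypes at deficiency variants contribute no allele copies.
    """
    deficiency = [v for v in catalog.deficiency_variants() if v.variant_id in matrix.dosages.columns]
    activities = {v.variant_id: v.allele_activity for v in deficiency}
    order = [v.variant_id for v in deficiency]
    rows = []
    for sample_id, dosages in matrix.dosages.iterrows():
        score, contributing, compound = _sample_activity(dosages, activities, order)
        rows.append(
            {
                "sample_id": sample_id,
                "activity_score": score,
                "contributing_alleles": ";".join(
                    f"{vid}x{n}" for vid, n in contributing
                ),
                "compound_warning": compound,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def classify_risk(
    activity: pd.DataFrame,
    matrix: GenotypeMatrix,
    hfs_variants: tuple[str, ...] = DEFAULT_HFS_VARIANTS,
) -> pd.DataFrame:
    """Four-tier risk classification from activity scores and HFS carriage.

    ``activity`` is the output of :func:`activity_score`. The tier is a
    total function of (activity score, HFS-allele carriage); the rationale
    string names the triggering alleles.
    """
    present_hfs = [v for v in hfs_variants if v in matrix.dosages.columns]
    hfs_dosage = matrix.dosages[present_hfs] if present_hfs else pd.DataFrame(index=matrix.dosages.index)
    rows = []
    for sample_id, rec in activity.iterrows():
        score = float(rec["activity_score"])
        if score in (0.0, 0.5):
            tier = RiskTier.CRITICAL
            rationale = (
                f"activity score {score:g} "
                f"({rec['contributing_alleles'] or 'no alleles'})"
            )
        elif score in (1.0, 1.5):
            tier = RiskTier.HIGH
            rationale = (
                f"activity score {score:g} ({rec['contributing_alleles']})"
            )
        else:
            carried = [
                vid
                for vid in present_hfs
                if pd.notna(hfs_dosage.at[sample_id, vid])
                and hfs_dosage.at[sample_id, vid] > 0
            ]
            if carried:
                tier = RiskTier.STANDARD_HIGH_HFS
                rationale = "activity score 2; HFS risk allele(s) " + ",".join(
                    f"{vid}x{int(hfs_dosage.at[sample_id, vid])}" for vid in carried
                )
            else:
                tier = RiskTier.STANDARD
                rationale = "activity score 2; no HFS risk alleles"
        rows.append(
            {
                "sample_id": sample_id,
                "activity_score": score,
                "tier": tier.value,
                "rationale": rationale,
                "compound_warning": bool(rec["compound_warning"]),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def tier_counts(tiers: pd.DataFrame) -> dict[str, int]:
    """Count samples per tier (all four tiers always present in the map)."""
    counts = Counter(tiers["tier"]) if len(tiers) else Counter()
    return {tier.value: int(counts.get(tier.value, 0)) for tier in RiskTier}
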