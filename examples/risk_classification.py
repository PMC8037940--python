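"""DPD activity scores and four-tier risk classification for a handful of
patients with hand-specified genotypes.

Builds five patients — a compound no-function homozygote, a no-function +
HapB3 compound heterozygote, a single HapB3 carrier, an ENOSF1 HFS-allele
carrier, and a patient with no risk alleles — and prints their activity
scores, tiers and the clinical recommendation attached to each tier.
"""

import pandas as pd

from fluoropanel import GenotypeMatrix, activity_score, classify_risk, default_catalog
from fluoropanel.scoring import TIER_RECOMMENDATIONS, RiskTier

catalog = default_catalog()

patients = {
    "P1_hom_no_function": {"rs1801266": 2},
    "P2_compound_het": {"rs3918290": 1, "rs56038477": 1},
    "P3_hapb3_carrier": {"rs56038477": 1},
    "P4_hfs_allele": {"rs2612091": 1},
    "P5_no_risk_alleles": {},
}
data = {v.variant_id: [0.0] * len(patients) for v in catalog.variants}
for i, doses in enumerate(patients.values()):
    for vid, dose in doses.items():
        data[vid][i] = float(dose)
matrix = GenotypeMatrix(
    pd.DataFrame(data, index=pd.Index(patients, name="sample_id"))
)

tiers = classify_risk(activity_score(matrix, catalog), matrix)
print(tiers[["activity_score", "tier", "rationale"]].to_string())
print()
for tier in RiskTier:
    if tier.value in set(tiers["tier"]):
        print(f"{tier.value}: {TIER_RECOMMENDATIONS[tier]}")

# The activity score sums the two least-active DPYD alleles (normal allele
# = 1.0), so P1 (two no-function copies) scores 0 and must avoid 5-FU,
# while P4 keeps normal DPD activity (score 2) but carries an allele that
# roughly doubles hand-foot-syndrome risk.
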