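"""Diagnostic accuracy of the CPIC four-variant panel on a synthetic cohort.

Scores every patient by summed risk-allele count (test positive at >= 1
allele), collapses graded toxicity to binary outcomes, and prints the 2x2
table with sensitivity, specificity, predictive values and likelihood
ratios for two outcomes.
"""

from fluoropanel import (
    allele_sum_score,
    binarize,
    confusion,
    default_catalog,
    default_config,
    diagnostic_metrics,
    derive_haematological,
    grade_good_test,
    simulate_cohort,
)

catalog = default_catalog()
cohort = simulate_cohort(default_config(seed=42))
tox = derive_haematological(cohort.toxicity)

scores = allele_sum_score(cohort.genotypes, catalog.model("model1"))
print(f"model1 positive tests: {int(scores.scores['positive'].sum())}"
      f" / {len(scores.scores)} patients\n")

for endpoint, coding in [("haematological", "g012_v_34"), ("hfs", "g012_v_34")]:
    outcome = binarize(tox, endpoint, coding)
    ct = confusion(scores.scores["positive"], outcome)
    m = diagnostic_metrics(ct)
    print(f"{endpoint} ({coding}): n={ct.n}, "
          f"tp={ct.tp} fp={ct.fp} tn={ct.tn} fn={ct.fn}")
    print(f"  sensitivity {m.sensitivity:.2f} "
          f"({m.sensitivity_ci[0]:.2f}-{m.sensitivity_ci[1]:.2f}), "
          f"specificity {m.specificity:.2f} "
          f"({m.specificity_ci[0]:.2f}-{m.specificity_ci[1]:.2f})")
    print(f"  PPV {m.ppv:.2f}, NPV {m.npv:.2f}, "
          f"LR+ {m.lr_plus:.2f}, LR- {m.lr_minus:.2f} "
          f"-> {grade_good_test(m)}\n")

# The DPD-deficiency panel picks up a share of haematological events at
# high specificity, but has almost no sensitivity for hand-foot syndrome
# (whose risk alleles are not in the panel): a 'good' rule-in test needs
# LR+ > 10 and LR- < 1.
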