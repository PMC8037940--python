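"""ROC power calculations for rare and common toxicity outcomes.

Uses the Hanley-McNeil binormal-variance approximation to ask: with the
case/control split a trial actually yields, how strong must a panel's AUC
be before the study can distinguish it from chance (AUC 0.5)?
"""

from fluoropanel import min_detectable_auc, roc_power

print("rare outcome: 4 grade-4 haematological events vs 884 unaffected")
for auc in (0.80, 0.85, 0.90, 0.95, 0.99):
    p = roc_power(auc, n_pos=4, n_neg=884)
    print(f"  power to detect AUC {auc:.2f}: {p.power:.2f}")

print("\ncommon outcome: ~1 in 4 patients with a grade >= 3 event")
auc_needed = min_detectable_auc(n_pos=222, n_neg=666, power=0.80)
print(f"  minimum AUC detectable at 80% power: {auc_needed:.3f}")

# With only 4 cases, even a strong panel (AUC 0.8) is hard to confirm;
# power reaches 80% only for AUC above ~0.87. For common outcomes the same
# cohort can detect AUCs barely above chance, so null results for rare
# endpoints are uninformative rather than reassuring.
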