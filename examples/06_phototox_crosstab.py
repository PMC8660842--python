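"""Cross-tabulate spectrum class against 3T3 NRU phototoxicity outcomes.

Treating the POS spectrum class as a toxicity alarm gives high sensitivity
but low specificity: light absorption is necessary, not sufficient, for
phototoxicity. The example compares a classifier-derived cross-tab with one
built from experimental spectrum classes over the same 43-molecule cohort.
"""

from photoreact.phototox import CrossTab, compare_predictors

predicted = CrossTab(toxic_pos=16, toxic_neg=3, nontoxic_pos=15, nontoxic_neg=9)
experimental = CrossTab(toxic_pos=15, toxic_neg=4, nontoxic_pos=12, nontoxic_neg=12)

for name, ct in [("predicted", predicted), ("experimental", experimental)]:
    s = ct.summary()
    print(f"{name:12s} se={s['se_tox']} sp={s['sp_tox']} concordant={s['concordant']}/{ct.n}")

cmp = compare_predictors(predicted, experimental)
print("cell deltas (predicted - experimental):", cmp["cell_deltas"])

# Both routes agree closely (25 vs 27 of 43 concordant): an ML spectrum
# class carries nearly the same phototoxicity signal as the experimental
# peak lists it was trained to reproduce.
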