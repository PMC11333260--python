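"""Phenome-wide batch MR screen with Bonferroni control.

Screens one instrument set against 20 simulated outcome GWASs of which
exactly one carries a true effect; significance is judged on the primary
IVW p-value at alpha / n_outcomes.
"""

import drugtarget_mr as dm

data = dm.simulate_mediation_gwas(dm.SimulationTruth(seed=3), seed=3)
inst = data.exposure_instruments()
panel, labels = dm.simulate_outcome_panel(inst, n_outcomes=20, n_true=1,
                                          true_effect=-0.5, seed=3)

res = dm.screen_outcomes(inst, panel, alpha=0.05, seed=3)
sig = res.significant
print(f"outcomes screened: {res.n_tests}, Bonferroni alpha = {res.adjusted_alpha:.2e}")
print(f"significant outcomes: {list(sig['outcome_label'])}")
truly = [t.trait_label for t, flag in zip(panel, labels) if flag]
print(f"outcomes simulated with a true effect: {truly}")
print("\nthe screen recovers exactly the outcome that truly responds to the")
print("instrumented exposure; null outcomes stay below the corrected level.")
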