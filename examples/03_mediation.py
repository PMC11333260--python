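"""Two-step / multivariable MR mediation decomposition.

The simulated DAG routes part of the exposure's effect on the outcome
through a metabolite mediator; the proportion mediated is
theta_xm * theta_my / theta_total, here 0.1/1.0 = 10%.
"""

import drugtarget_mr as dm

truth = dm.SimulationTruth(theta_xm=0.4, theta_my=0.25, theta_direct=0.9, seed=2)
data = dm.simulate_mediation_gwas(truth, seed=2)

res = dm.two_step_mediation(
    data.exposure_instruments(), data.mediator, data.mediator_instruments(),
    data.outcome, seed=2, exposure_gwas=data.exposure,
)
print(f"beta1 (exposure -> mediator)          = {res.beta1:+.3f}")
print(f"beta2 (mediator -> outcome, UVMR)     = {res.beta2:+.3f}")
print(f"beta2' (mediator -> outcome, MVMR)    = {res.beta2_adj:+.3f}")
print(f"beta3 (total exposure -> outcome)     = {res.beta3:+.3f}")
print(f"proportion mediated (UVMR product)    = {100 * res.proportion_uvmr:.2f}%")
print(f"proportion mediated (MVMR product)    = {100 * res.proportion_mvmr:.2f}%")
print(f"simulated truth                       = {100 * truth.proportion_mediated:.2f}%")
print("\nbeta2' is the mediator effect conditional on the exposure; the MVMR")
print("product beta1*beta2'/beta3 is the share of the total effect carried")
print("by the mediator pathway.")
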