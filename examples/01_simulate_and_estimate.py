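"""Simulate an illness-death study and estimate separable effects.

Draws a 400-subject two-arm study (healthy -> ill -> dead with direct
deaths and right censoring), fits the default working models (main-effects
logistic propensity, main-effects Cox transition hazards, covariate-free
censoring Cox) and prints the separable direct effect (SDE), separable
indirect effect (SIE) and total effect (TE) of treatment on the risk of
death, with bootstrap confidence intervals.

A negative SDE means the treatment component acting directly on death is
protective at that horizon; a negative SIE means the component acting
through illness is protective; TE = SDE + SIE is the usual total effect of
treatment on mortality risk.
"""

import sepid as sp

config = sp.make_scenario(1, "i", n=400, seed=7)
data = sp.simulate_observed_study1(config)
print(f"simulated {data.n} subjects: "
      f"{data.illness.sum()} became ill, {data.death.sum()} died observed")

result = sp.bootstrap_ci(data, tau_grid=[5.0, 15.0, 25.0],
                         estimator="one_step", n_boot=100, seed=1)
table = result.to_frame()
print(table[table.estimand.isin(["sde", "sie", "te"])].to_string(index=False))

truth, mc_se = sp.true_sde_mc(config, a_i=1, tau=15.0, n_mc=200_000, seed=3)
print(f"\ntrue SDE(tau=15, aI=1) from the counterfactual oracle: {truth:+.4f}"
      f" (MC se {mc_se:.4f})")
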