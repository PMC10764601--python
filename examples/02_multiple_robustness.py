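"""Multiple robustness of the one-step estimator.

Under a misspecified 1->3 (direct death) hazard — the working Cox model
omits a treatment-by-covariate interaction present in the generating
process — the G-computation plug-in inherits the misspecification while
the one-step estimator, which adds inverse-probability-weighted martingale
corrections, remains approximately unbiased as long as the other nuisance
models are correct.

A small replication (40 datasets) is enough to see the gap; the bias
column is estimate minus the Monte-Carlo counterfactual truth.
"""

import sepid as sp

summary = sp.run_simulation_study(
    1, ["iv"],               # gamma13 != 0: the 1->3 hazard model is wrong
    n_datasets=40, n=400, tau_grid=[15.0, 25.0],
    master_seed=5, n_mc_truth=200_000)

cols = ["scenario", "estimator", "tau", "bias", "empirical_se", "truth"]
print(summary.table[cols].to_string(index=False))
print("\nThe plug-in bias grows with the horizon; the one-step bias stays "
      "within Monte-Carlo noise.")
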