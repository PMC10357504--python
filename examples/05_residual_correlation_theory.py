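"""How shared pleiotropy induces residual correlation between outcomes.

Sweeps the pathway effect thetaA and compares three quantities: the raw
empirical correlation between outcome summary statistics, the model's
posterior-mean residual correlation, and the closed-form prediction.  The
empirical correlation cannot distinguish exposure-driven correlation from
unmeasured shared pleiotropy; the residual correlation isolates the
latter.
"""

import numpy as np

import mr2

print(f"{'thetaA':>7} {'theory':>7} {'estimated':>10} {'empirical':>10}")
for theta_a in (0.25, 1.0, 2.0):
    cfg = mr2.ScenarioConfig(scenario="III_undirected_pleiotropy",
                             theta_a=theta_a, seed=30)
    summ, _ = mr2.simulate_summary(cfg)
    emp = mr2.empirical_outcome_correlation(summ)[np.triu_indices(5, 1)].mean()
    ch = mr2.fit_mr2(summ, n_iter=1500, n_burnin=600, seed=0)
    est = ch.R.mean(axis=0)[np.triu_indices(5, 1)].mean()
    theory = mr2.expected_residual_correlation(cfg)
    print(f"{theta_a:7.2f} {theory:7.3f} {est:10.3f} {emp:10.3f}")

print("\nThe estimate tracks the closed-form value; the empirical")
print("correlation sits above both because it also absorbs the")
print("correlation created by shared causal exposures.")
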