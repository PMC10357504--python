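"""Simulate a two-sample GWAS study and inspect the summary statistics.

Generates one replicate of the confounding scenario (15 exposures, 5
outcomes, 100 variants, 100,000 individuals split half for the exposure
GWAS, half for the outcome GWAS) and prints the dimensions, the realized
exposure-effect sparsity, and the empirical correlation between the
outcome summary statistics.
"""

import numpy as np

import mr2

cfg = mr2.ScenarioConfig(scenario="II_confounding", seed=1)
summ, truth = mr2.simulate_summary(cfg)

print(f"variants n={summ.n}, exposures p={summ.p}, outcomes q={summ.q}")
print(f"nonzero direct effects: {truth.true_gamma.sum()} of "
      f"{truth.true_gamma.size} pairs "
      f"({truth.true_gamma.mean():.0%}, design target 30%)")

C = mr2.empirical_outcome_correlation(summ)
off = C[np.triu_indices(summ.q, 1)]
print(f"empirical outcome correlation: mean {off.mean():.3f} "
      f"(range {off.min():.3f} to {off.max():.3f})")
print("This raw correlation mixes exposure-driven and residual components;")
print("separating them is what the multi-response model is for.")
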