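# mr2 — multi-response Mendelian randomization

Mendelian randomization (MR) uses genetic variants as instrumental
variables to estimate the causal effect of exposures on a disease
outcome from GWAS summary statistics.  Standard multivariable MR handles
many exposures but only **one outcome at a time**, which is the wrong
tool when the scientific question is about *multimorbidity*: which risk
factors are shared causes of several related diseases, and which are
specific to one?

This package implements a sparse Bayesian **multi-response** MR model.
For each variant i, the q-vector of variant-outcome associations is
modelled jointly as a seemingly unrelated regression system

    beta_Y[i] ~ N_q( Theta_Gamma beta_X[i],  D^{1/2} R D^{1/2} ),

where `Theta` (q x p) holds the direct causal effects under a
spike-and-slab prior (point mass at zero for excluded exposure-outcome
pairs, Gaussian slab otherwise), `D` the per-outcome overdispersions,
and `R` the **residual correlation** between outcomes — the correlation
that the exposures cannot explain, which arises from unmeasured shared
pleiotropic pathways and from non-genetic factors affecting several
outcomes.  `R` carries a hyper-inverse Wishart prior on a decomposable
graph, so its inverse has exact zeros where two outcomes are
conditionally independent.  An MCMC sampler with collapsed
(marginalized-effect) selection moves explores exposure subsets and the
residual graph jointly; posterior inclusion probabilities (mPPI per
pair, ePPI per residual edge, jPPI per exposure across an outcome set)
quantify the evidence, with mixture-model Bayesian FDR selection and CPO
outlier screening of individual variants on top.

A full synthetic-study engine (individual-level generating model,
two-sample summary extraction, five canonical scenarios), the classical
per-outcome baselines (IVW, MV-MR, MV-MR-Egger) and a benchmark harness
(ROC/AUC, SSE, shared-effect power) are included.  See
`docs/methods.md` for the model, priors, generator conventions and
limitations.

## Worked example

`examples/02_fit_multi_response_model.py` simulates the
shared-pleiotropy scenario (15 exposures, 5 outcomes, 100 variants,
an unmeasured pathway with effect 1 on every outcome) and fits the
model:

```text
acceptance rates: {'flip': 0.113, 'swap': 0.073, 'edge': 0.231}

top exposure-outcome pairs by mPPI (true effect in brackets):
   Y1 <- X9  mPPI 1.00  theta +0.403 [true +0.295]
   Y2 <- X13 mPPI 1.00  theta +0.382 [true +0.273]
   Y3 <- X13 mPPI 1.00  theta +0.270 [true +0.218]
   Y5 <- X5  mPPI 1.00  theta +0.159 [true +0.157]
   ...

AUC of mPPI against the simulated truth: 0.987
SSE of posterior-mean effects: 0.162

posterior mean residual correlation (mean off-diagonal): 0.401
closed-form prediction for this design: 0.518
```

Reading this: every pair with mPPI near 1 is confidently causal, and
the posterior-mean effects sit close to the simulated truth.  The
sampler's estimate of the residual correlation between outcomes (0.40
in this replicate) sits near the closed-form value implied by the
generating model (0.52) — the correlation produced by the shared
pathway that the exposures cannot explain; averaged over replicates the
estimate tracks the prediction (example `05` and the test-suite do that
sweep).  The other example scripts cover simulation
and inspection (`01`), FDR selection, jPPI and CPO outliers (`03`), a
benchmark against per-outcome MV-MR (`04`) and the
residual-correlation theory sweep (`05`).

There is also a thin CLI over the same functions:

```sh
mr2 simulate --scenario III_undirected_pleiotropy --seed 1 --out-dir sim/
mr2 fit --input sim/replicate_000.tsv --n-iter 5000 --burnin 2000 --out-prefix run
mr2 summarize --chains run_chains.npz --input sim/replicate_000.tsv --out-dir summary/
mr2 benchmark --scenario II_confounding --methods mvmr mr2 --replicates 5 --out bench.csv
```

Input files are TSV/CSV with a `variant` column and `beta_<trait>` /
`se_<trait>` pairs per exposure and outcome.

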