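# Methods

## Problem and model

Two-sample summary-level Mendelian randomization treats each genetic
variant as one observation: the variant's association with the outcome is
regressed on its associations with the exposures, using variants as
instrumental variables.  This package models **q outcomes jointly**.  For
variant i with IVW-standardized association vectors, the model is a
seemingly unrelated regression (SUR) system

    beta_Y[i] ~ N_q( mu + Theta_Gamma beta_X[i], D^{1/2} R D^{1/2} ),

with

* `Theta` — q x p matrix of direct causal effects; a spike-and-slab prior
  puts a point mass at zero on excluded exposure-outcome pairs and a
  Gaussian slab N(0, `slab_variance`) on included ones.  The binary
  inclusion matrix `Gamma` carries an exchangeable beta-binomial prior
  (Beta(`inclusion_a`, `inclusion_b`) on the inclusion probability,
  integrated out).
* `D = diag(delta_k^2)` — per-outcome overdispersions (multiplicative
  inflation of the first-order IVW variance).
* `R` — residual correlation between outcomes after conditioning on the
  selected exposures.  Its inverse carries exact zeros off the edges of a
  decomposable graph G; the covariance `Sigma = D^{1/2} R D^{1/2}` has a
  hyper-inverse Wishart prior HIW(`hiw_df`, `hiw_scale` * I) on G, and
  each edge of G an independent Bernoulli(`edge_prior`) prior.
* `mu` — response-specific intercepts, off by default (the standard MR
  convention); enabling them absorbs directional pleiotropy shifts.

Exposures may only point at outcomes: no reverse causation and no
exposure-exposure or outcome-outcome directed effects are modelled.

### Why residual correlation matters

If an unmeasured pathway A (effect `theta_a` on every outcome, variance
`sigma2_a`) is a descendant of the instruments, the residuals of the
per-outcome summary models are correlated

    rho = (theta_a^2 sigma2_a + sigma_kk')
          / sqrt(theta_a^2 sigma2_a + delta_k^2)
          / sqrt(theta_a^2 sigma2_a + delta_k'^2),

where `sigma_kk'` is the covariance of the individual-level outcome
errors.  The contribution of shared pleiotropy is always positive,
whatever the sign of `theta_a`, and survives zero sample overlap through
the genetic component of the pathway.  `theoretical_residual_correlation`
implements this formula; `residual_correlation_arguments` maps a simulation
configuration onto its argument slots (see below).

## Sampler

One iteration cycles three blocks (all moves seeded, chains reproducible
bit-for-bit given the seed):

1. **Selection/estimation.** `moves_per_iter` (default max(10, p))
   single-pair proposals: with probability 1/2 a uniform flip of one
   (outcome, exposure) indicator, otherwise a within-outcome swap of one
   active against one inactive exposure (both symmetric).  Because the
   slab is Gaussian and Sigma is held fixed during the sweep, the nonzero
   effects can be integrated out analytically; the Metropolis-Hastings
   ratio reduces to a ratio of collapsed Gaussian marginal likelihoods
   times beta-binomial prior odds, so the proposal of the paired effect
   values cancels exactly ("implicit marginalization").  After the sweep
   the active effects are redrawn from their exact Gaussian full
   conditional.  A ridge jitter of 1e-8 guards degenerate designs.
2. **Graph.** One uniformly chosen edge is toggled.  Proposals leaving
   the decomposable family are rejected outright (chordality via
   maximum-cardinality search).  Otherwise the move is accepted with the
   ratio of closed-form HIW marginal likelihoods of the current residuals
   (covariance integrated out clique-by-clique) times the edge prior
   odds.  Cliques and separators come from a maximum-weight spanning tree
   of the clique-intersection graph; junction trees are cached per
   adjacency.
3. **Covariance.** Sigma is drawn exactly from its HIW full conditional
   by sequential clique sampling (inverse-Wishart per clique via the
   Bartlett construction, conditionally adjusted to agree on separators)
   followed by precision-space completion, then re-expressed as
   (`delta2`, `R`).  Updating the graph marginally over Sigma and then
   redrawing Sigma is a valid partially collapsed step.

Defaults: `slab_variance=1` (on the IVW-standardized scale),
Beta(1,1) inclusion prior, HIW(3, I), `edge_prior=0.5`,
`n_iter=15000` post-burn-in after `n_burnin=5000`.  For the simulation
studies in the test-suite and the acceptance script, chains are shortened
to 1200–2000 post-burn-in draws, which is sufficient for stable mPPI
ranking at p=15, q=5 (verified against exhaustive enumeration on small
instances).  A fixed-correlation mode (R = I held fixed, `delta2` updated
from its exact inverse-gamma full conditional using `delta_shape`,
`delta_rate`) exists for validation; in the full model the
overdispersions are the diagonal of the HIW covariance draw.

With a single outcome and fixed support the sampler degenerates to exact
Gibbs draws from the conjugate Bayesian linear model, and its posterior
means agree with MV-MR up to shrinkage — both properties are asserted in
the tests.

## Post-processing

* **mPPI / ePPI / jPPI** — posterior frequencies of a pair's inclusion,
  an edge's presence, and an exposure's simultaneous inclusion across a
  set of outcomes.  jPPI <= min mPPI over the set, always.
* **Effect summaries** — posterior means and credible intervals both
  unconditionally (zeros from excluded draws count, the right estimate
  for SSE-type loss) and conditionally on inclusion.
* **Partial correlations** — from each draw's R by inverse-normalization;
  exactly zero off the graph.
* **FDR selection** — a two-component Beta mixture is fitted to the PPIs
  by EM (10 random restarts; weighted Beta MLE by Newton on the digamma
  equations).  The low-mean component's posterior weight is a local null
  probability; the threshold is the smallest PPI whose selected set keeps
  the average null probability at or below the target level.  Degenerate
  fits (single cluster, identical PPIs) fall back to the 0.5
  median-probability-model rule with a warning.  The mixture is a
  parametric stand-in for the non-parametric two-group approach; it is
  transparent and its calibration is tested on synthetic mixtures with
  known labels.
* **CPO** — the conditional predictive ordinate per variant, the harmonic
  mean over draws of the variant's observation density, computed in log
  space (log-sum-exp; no overflow for near-zero densities).  "Scaled CPO"
  divides by the maximum across variants — a unit-free convention chosen
  here because the quantity is only used relatively; the default outlier
  threshold is scaled CPO < 0.01.  Intended workflow: flag, remove,
  refit.

## Synthetic data generator

The generator emulates a two-sample multi-outcome GWAS design:

    Y_k = X theta_k + A theta_a + U theta_yu + eps_k.

* **Genotypes** — n=100 independent biallelic dosages, allele
  frequencies Uniform(0.05, 0.5) (independence standing in for LD
  pruning).
* **Exposures** — X_j = sqrt(r_x) S + sqrt(1-r_x) F_j with S, F_j
  independent unit-variance traits, each with heritability `h_gx`
  through the instruments.  Both the phenotypic and the genetic pairwise
  exposure correlation equal r_x (default 0.6), so the exposure summary
  statistics are collinear the way real co-regulated risk factors are.
  The confounder U loads on the non-genetic part of S with weight
  `theta_xu` (default 2) and on every outcome with `theta_yu` (default
  1).
* **Effects** — 30% of the q x p pairs carry a direct effect with
  magnitude Uniform(0.1, 0.3).  Signs are positive by default: concordant
  risk-factor effects are the epidemiologically typical case and are what
  makes the raw outcome correlation exceed the residual correlation;
  `signed_effects=True` randomizes signs.
* **Pathway** — A = genetic component (heritability `h_ga`, default
  0.005) plus Gaussian noise, total variance `sigma2_a`=1; symmetric
  about zero in the undirected scenario, absolute-valued (A_l > 0) in the
  directed one.  The small genetic component models a polygenic pathway
  weakly tagged by the selected IVs; it is what keeps pathway-driven
  residual correlation alive when outcome samples do not overlap.
* **Noise scale** — `h_x` (default 0.10) fixes
  Var(X theta_k) / (Var(X theta_k) + delta_k^2); pathway and confounder
  variance sit on top of that budget.  (Interpreting h_x against *total*
  outcome variance would make delta_k^2 negative at theta_a >= 1 with the
  stated confounder effects, so this ratio convention is used.)
* **Extraction** — per-variant univariable OLS with intercept; the first
  N/2 individuals give the exposure GWAS, the second N/2 the outcome
  GWAS, with `overlap` controlling how much the per-outcome samples
  share (1.0 = identical, 0.0 = disjoint N/(2q) subsamples).
* **Scenarios** — I: global null, no confounder, r_y=0.6; II: confounding
  only; III/IV: undirected/directed shared pathway (theta_a defaults
  to 1); V: equicorrelated outcome errors r_y=0.6.

Two constants the design leaves open — `h_gx` and the effect range — were
calibrated once so that the per-outcome MV-MR baseline lands near its
reference operating point (AUC about 0.92 under confounding), and then
frozen; `h_gx=0.125` corresponds to per-variant F-statistics around 60 at
N/2 = 50,000, i.e. comfortably strong but realistic instruments.

Because every *shared* stochastic component of the outcome GWAS — the
non-genetic pathway part, the confounder, the non-genetic exposure parts
carried by the causal effects, correlated errors, and (always) the
exposure-GWAS estimation noise — enters the summary-level residual
covariance under sample overlap, the honest closed-form prediction for
the generator evaluates the residual-correlation formula at *effective*
arguments accumulating those pieces (`residual_correlation_arguments`).  Tests
compare the sampler's posterior residual correlation against that
prediction across the pathway-effect grid.

What the generator does **not** emulate: LD between variants, binary
(case-control) outcomes, allele-coding/harmonization artefacts, winner's
curse from instrument selection, and population stratification.  Passing
tests therefore demonstrate correctness of the method under its own
assumptions, not robustness to those real-data complications.

## Benchmark harness

AUC is the tie-corrected Mann-Whitney statistic over all q x p pairs
(mPPI for the Bayesian model, 1 - p-value for MV-MR/IVW); SSE compares
unconditional posterior means (zeros where excluded) or WLS estimates
with the simulated truth.  Replicates are seeded through
`numpy.random.SeedSequence` spawning, so results are reproducible
regardless of method order.  The shared/distinct power analysis fixes the
number of false positives across methods before counting detections,
stratified by how many outcomes truly share the exposure.

The test-suite and `scripts/acceptance.py` use 10–50 replicates per
scenario with shortened chains; at those sizes the replicate SDs of the
metrics are the relevant uncertainty and are reported alongside.

## Known limitations

* The decomposable-graph restriction means non-decomposable dependence
  patterns are approximated by their closest chordal cover; at q=5 this
  is minor (all graphs on <= 3 nodes are decomposable).
* The Beta-mixture FDR selection needs enough spread in the PPIs; with
  fewer than ~8 items or a single cluster it falls back to the 0.5 rule.
* `per_outcome` standardization is limited to q=1 by construction; the
  joint-precision weights assume the per-outcome standard errors are of
  comparable scale across outcomes (true after per-outcome scaling of
  the input GWAS, as is conventional).
* Overdispersions and R are identified through the HIW prior; with very
  few variants (n below roughly q(p+1) + q(q-1)/2) the posterior is
  prior-dominated and the fitter warns.
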