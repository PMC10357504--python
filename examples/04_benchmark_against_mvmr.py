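"""Small benchmark: multi-response model vs per-outcome MV-MR.

Runs a few replicates of the undirected-pleiotropy scenario and compares
the two methods on exposure discrimination (AUC of mPPI vs 1-p-value) and
direct-effect estimation (SSE).  With a shared pleiotropic pathway the
joint model borrows strength across outcomes through the residual
correlation and both detects and estimates better.
"""

import mr2

res = mr2.run_benchmark(scenario="III_undirected_pleiotropy",
                        methods=("mvmr", "mr2"), replicates=4, seed=0,
                        mr2_kwargs={"n_iter": 2000, "n_burnin": 1000})
print(res.table()[["method", "auc_mean", "auc_sd", "sse_mean", "sse_sd"]]
      .to_string(index=False))
print("\nHigher AUC = better separation of causal from null exposures;")
print("lower SSE = more accurate direct-effect estimates.")
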