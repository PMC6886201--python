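"""Simulate a small RNA-seq experiment and run the joint l0 fit.

Generates counts for 2000 genes x 20 samples with 30% DE genes (all
up-regulated, the hard asymmetric case for scaling-factor normalization),
then fits the joint model and compares the estimated per-sample offsets
d_j with the true log sequencing depths.
"""

import numpy as np

from jointde import (
    CovariateMatrix,
    SimulationConfig,
    estimate_noise_variances,
    fit_type1,
    log_transform,
    select_lambda,
    simulate_dataset,
)

cfg = SimulationConfig(m=2000, n=20, de_fraction=0.30, up_fraction=1.0,
                       noise="lognormal", seed=42)
sim = simulate_dataset(cfg)
Y = log_transform(sim)                       # log(counts + 1)
X = CovariateMatrix(sim.covariates)

variances = estimate_noise_variances(Y, X)   # alternating MLE + shrinkage
lam = select_lambda(q=0.01, p=1, penalty_type="type1")
fit = fit_type1(Y, X, variances, lam)

true_depth = np.log(sim.library_sizes) + sim.sample_offsets
r = np.corrcoef(fit.d, true_depth)[0, 1]
tp = (fit.selected & sim.de_labels).sum()
fp = (fit.selected & ~sim.de_labels).sum()

print(f"lambda at q=0.01:            {lam:.4f}")
print(f"shared slope delta:          {fit.delta[0]:.4f}")
print(f"genes selected as DE:        {fit.selected.sum()} "
      f"({tp} true positives, {fp} false positives of {sim.de_labels.sum()} DE)")
print(f"corr(d_hat, true log depth): {r:.4f}")
print()
print("delta is the precision-weighted mean effect shared by all genes; a")
print("correlation near 1 means the sample offsets d_j recovered the true")
print("sequencing depths even though 30% of genes are shifted upward.")
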