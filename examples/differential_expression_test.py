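"""Rank genes for differential expression after joint normalization.

After the fit, the estimated offsets d_j are subtracted from the data and
each gene is tested by an ordinary regression F-test, decoupled from all
other genes. The ranking is scored against the simulation truth by AUC.
"""

import numpy as np

from jointde import (
    CovariateMatrix,
    SimulationConfig,
    compute_auc,
    estimate_noise_variances,
    fit_type1,
    gene_pvalues,
    log_transform,
    select_lambda,
    simulate_dataset,
)

cfg = SimulationConfig(m=2000, n=20, de_fraction=0.10, up_fraction=0.5,
                       noise="negbinom", seed=3)
sim = simulate_dataset(cfg)
Y = log_transform(sim)
X = CovariateMatrix(sim.covariates)

fit = fit_type1(Y, X, estimate_noise_variances(Y, X), select_lambda(0.01))
pvalues = gene_pvalues(Y, X, fit, method="ols_f")
auc = compute_auc(pvalues, sim.de_labels)

order = np.argsort(pvalues)
print("top 5 genes by p-value (p, estimated beta, true beta):")
for i in order[:5]:
    print(f"  {sim.gene_ids[i]:>10}  p={pvalues[i]:.3g}  "
          f"beta_hat={fit.beta[i, 0]:+.2f}  beta_true={sim.truth_beta[i, 0]:+.2f}")
print(f"\nAUC of the DE ranking vs truth: {auc:.4f}")
print("AUC 1.0 would mean every truly DE gene outranks every null gene;")
print("0.5 would be a random ordering.")
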