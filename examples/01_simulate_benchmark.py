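"""Generate a benchmark dataset with a known differential co-expression network.

Counts come from zero-inflated negative binomial marginals coupled by a
Gaussian copula (NORTA); the two conditions share marginals but differ in the
latent correlation on a designed set of gene-group block pairs.
"""

import numpy as np

from facdiff import ZinbParams, build_block_design, norta_sample, truth_table

design = build_block_design(G=30, n_groups=10, n_diff_blocks=5,
                            delta_levels=(0.3, 0.6, 0.9), seed=1)
zinb = ZinbParams.random(30, seed=2)
dataset, _ = norta_sample(design, zinb, N0=200, N1=200, seed=3)

print(f"dataset: {dataset.n_genes} genes x {dataset.n_cells} cells "
      f"({np.sum(dataset.groups == 0)} control / {np.sum(dataset.groups == 1)} treatment)")
print(f"true differential edges: {len(design.true_diff)} of "
      f"{dataset.n_genes * (dataset.n_genes - 1) // 2}")
lo, hi = design.diff_magnitude_range
print(f"designed |delta rho| range: {lo:.2f} .. {hi:.2f}")
print(f"zero fraction of the counts: {np.mean(dataset.counts == 0):.2f}")

# The per-edge truth table is what detections are scored against.
truth = truth_table(design, dataset.gene_ids)
print(truth[truth.is_diff].head(3).to_string(index=False))
# Each row lists a gene pair with its designed control (rho0_true) and
# treatment (rho1_true) latent correlations; is_diff marks the edges a
# differential network method should recover.
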