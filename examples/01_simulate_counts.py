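"""Generate an overdispersed RNA-seq count study with planted signal.

Draws negative-binomial counts for 500 genes x 30 samples (15 per class),
with 2% of genes differentially expressed at |log2 fold change| = 2, and
prints the overdispersion the generator was asked for.
"""

import numpy as np

from gragp import SimConfig, simulate_counts

cfg = SimConfig(n_genes=500, n_per_class=(15, 15), de_fraction=0.02, dispersion=0.2, seed=1)
cm, labels, truth = simulate_counts(cfg)

print(f"count matrix: {cm.n_genes} genes x {cm.n_samples} samples")
print(f"library sizes: {cm.library_sizes().min()} .. {cm.library_sizes().max()}")

ratio = cm.counts.var(axis=1, ddof=1) / np.maximum(cm.counts.mean(axis=1), 1e-9)
print(f"median per-gene variance/mean ratio: {np.median(ratio):.1f}")
print(f"planted DE genes: {sorted(truth.de_gene_ids)}")

# A variance/mean ratio well above 1 is the overdispersion that makes the
# negative binomial (not the Poisson) the right count model here.
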