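"""Transform counts to log2-CPM with precision weights.

The voom-style transform regresses each gene's log-CPM on the class design,
smooths sqrt residual standard deviation against mean log2 count, and turns
the fitted trend into per-observation inverse-variance weights.
"""

import numpy as np

from gragp import SimConfig, simulate_counts, voom

cm, labels, _ = simulate_counts(
    SimConfig(n_genes=800, n_per_class=(12, 12), de_fraction=0.0, dispersion=0.2, seed=2)
)
tm = voom(cm, labels)

print(f"values: {tm.values.shape}, range {tm.values.min():.2f} .. {tm.values.max():.2f} log2-CPM")
print(f"weights: all positive = {bool((tm.weights > 0).all())}")

# Weights should grow with abundance: NB counts are noisiest (on the log
# scale) for low-expressed genes.
order = np.argsort(cm.counts.mean(axis=1))
low, high = order[:100], order[-100:]
print(f"mean weight, 100 lowest-expressed genes:  {tm.weights[low].mean():8.2f}")
print(f"mean weight, 100 highest-expressed genes: {tm.weights[high].mean():8.2f}")
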