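"""Classify held-out samples with a Gaussian-process model on selected genes.

Trains on two thirds of the samples (voom, scoring, GRA top-5 selection and
GP fitting all on the training part only) and predicts the rest.
"""

import numpy as np

from gragp import (
    GPConfig,
    SimConfig,
    gp_predict,
    gp_train,
    score_all,
    select_top_k,
    simulate_counts,
    voom,
)
from gragp.voom import log_cpm

cm, labels, _ = simulate_counts(
    SimConfig(n_genes=600, n_per_class=(15, 15), de_fraction=0.02, dispersion=0.2, seed=4)
)
rng = np.random.default_rng(0)
test_idx = np.sort(np.r_[rng.choice(15, 5, replace=False), 15 + rng.choice(15, 5, replace=False)])
train_idx = np.setdiff1d(np.arange(30), test_idx)

cm_tr, y_tr = cm.subset_samples(train_idx), labels.subset(train_idx)
tm = voom(cm_tr, y_tr)
_, genes = select_top_k(score_all(tm, y_tr), k=5)
model = gp_train(tm.subset_genes(genes).values.T, y_tr, GPConfig())

rows = [cm.gene_ids.index(g) for g in genes]
x_test = log_cpm(cm.subset_samples(test_idx))[rows].T
prob = gp_predict(model, x_test)

correct = 0
for i, p in zip(test_idx, prob):
    pred = int(p > 0.5)
    hit = pred == labels.labels[i]
    correct += hit
    print(f"sample {cm.sample_ids[i]}: P(class1) = {p:.3f} -> class {pred} "
          f"({'correct' if hit else 'wrong'})")
print(f"held-out accuracy: {correct}/{len(test_idx)}")
# Probabilities near 0 or 1 mean the posterior GP is confident; values near
# 0.5 mean the sample sits between the two classes in the selected gene space.
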