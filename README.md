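# gragp

Classification of RNA-seq read-count samples by **grey relational analysis
(GRA) feature selection** and **Gaussian-process (GP) classification**, with a
sparse Poisson LDA comparator, a repeated cross-validation harness, and a
negative-binomial count simulator.

The package is for bioinformaticians who start from a genes × samples table of
read counts plus a two-class sample annotation (tumor / normal, population A /
population B, …) and want a small, discriminative gene subset together with a
calibrated probabilistic classifier.

## The method

Raw counts are heteroscedastic, skewed and overdispersed (per-gene variance
μ + φμ² exceeds the mean), so they are first transformed to microarray-like
values: log₂ counts-per-million with a small offset, plus voom-style
precision weights obtained by smoothing √(residual sd) against mean log₂
count under a linear model with intercept, class and (optionally) batch
covariates.

Each gene *g* is then scored by five filter statistics on its transformed
values split by class (means μ₁, μ₂; sds σ₁, σ₂; sizes n₁, n₂):

* |t| = |μ₁ − μ₂| / √(σ₁²/n₁ + σ₂²/n₂)
* symmetric KL entropy  e = ½[σ₁²/σ₂² + σ₂²/σ₁² − 2 + (1/σ₁² + 1/σ₂²)(μ₁−μ₂)²]
* Bhattacharyya distance  BD = ¼ln(¼(σ₁²/σ₂² + σ₂²/σ₁² + 2)) + ¼(μ₁−μ₂)²/(σ₁²+σ₂²)
* |standardized Wilcoxon rank sum| (midranks, tie-corrected variance)
* folded empirical AUC, max(AUC, 1 − AUC)

GRA treats genes as alternatives and the five scores as criteria: each column
is min–max normalized to [0, 1], each cell is compared to the ideal all-ones
reference through the grey relational coefficient
δᵢⱼ = (Δmin + αΔmax)/(Δᵢⱼ + αΔmax) with Δᵢⱼ = |1 − xᵢⱼ| and α = 0.5, and the
weighted mean of a gene's five coefficients is its **grey relational grade**.
The top-k genes by grade feed a zero-mean GP binary classifier
(squared-exponential ARD kernel, logistic likelihood, Laplace inference,
marginal-likelihood hyperparameter optimization).

The comparator, sparse Poisson LDA, works on raw counts: X*ⱼ | k ~
Poisson(s\* gⱼ d_kⱼ) with total-count / median-ratio / 75th-percentile size
factors, profiles d_kⱼ soft-thresholded toward 1 by a tuning parameter ρ, and
assignment to argmaxₖ Σⱼ X*ⱼ log d_kⱼ − s\* Σⱼ gⱼ d_kⱼ + log πₖ.

Performance is measured by repeated stratified 5-fold cross-validation
(feature selection nested inside training folds) with accuracy, F-measure,
AUC and mutual information in percent, and method comparisons use a
two-sided Mann-Whitney rank-sum test.

## Worked example

```python
from gragp import (SimConfig, simulate_counts, voom, score_all,
                   select_top_k, recovery_report)

cm, labels, truth = simulate_counts(
    SimConfig(n_genes=1000, n_per_class=(40, 40), de_fraction=0.01,
              dispersion=0.2, seed=3))
tm = voom(cm, labels)
result, top10 = select_top_k(score_all(tm, labels), k=10)
print(recovery_report(top10, truth))
```

prints

```
{'n_selected': 10.0, 'n_de': 10.0, 'n_recovered': 10.0,
 'recall': 1.0, 'precision': 1.0, 'empty_selection': 0.0}
```

i.e. all ten genes planted at |log₂FC| = 2 under dispersion φ = 0.2 appear in
the grey-relational top ten. The scripts in `examples/` walk through each
capability (simulation, transformation, selection, GP classification, sPLDA,
cross-validation) with printed output; there is also a thin CLI
(`gragp simulate | transform | score | select | classify | evaluate |
compare`).

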