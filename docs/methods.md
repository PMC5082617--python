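# Methods

This note records the models the package implements, the defaults and why,
the numerical choices, and what the synthetic benchmark does and does not
establish.

## Count transformation

Counts are converted to log₂ CPM as
`log2((count + 0.5) / (libsize + 1) * 1e6)`; the 0.5 count offset (and twice
that on the library size) keeps zero counts finite and is the standard voom
dialect. A per-gene linear model on the sample-level design — intercept,
class indicator, and one indicator per extra batch level when a batch
covariate is supplied — yields residual standard deviations; a lowess smoother
(span 0.5, 3 robustness iterations) of √sd against mean log₂ count gives the
mean–variance trend, interpolated linearly and extrapolated flat so predicted
standard deviations stay positive outside the fitted range. Each
observation's fitted log₂ count is pushed through the trend and raised to the
−4th power to give an inverse-variance precision weight. Degenerate genes
with zero residual variance have √sd floored at 1e−6.

Two deliberate design points:

* The batch covariate always enters the *variance* model (and hence the
  weights); the transformed *values* are only batch-corrected when
  `remove_batch=True`. Both behaviours are exposed because either is a
  defensible reading of "addressing the batch effect", and downstream scores
  may legitimately want uncorrected values with batch-aware weights.
* The filter scores consume the transformed values unweighted. The five
  scoring formulas are defined on plain samples; the weights' role here is to
  justify treating log-CPM as approximately Gaussian, not to reweight the
  statistics.

## Filter scores

All five scores are non-negative magnitudes, invariant to swapping the class
labels. Sample standard deviations use the unbiased (n−1) denominator. Two
numerical guards: when a class is constant, variances are floored at 1e−8 for
the entropy and Bhattacharyya formulas (keeps scores finite, preserves
ordering), and the t score is capped at 1e8 when the pooled variance is zero
but the means differ — perfect separation should rank top, not crash. The
Wilcoxon statistic is the midrank sum of the smaller group, standardized with
the tie-corrected variance n_s·n_o·(n + 1 − Σ(t³−t)/(n(n−1)))/12; with all
pooled values identical the score is defined as 0. The empirical AUC is
computed through the rank identity (U/(n₁n₂), ties counted half) and folded
as max(AUC, 1−AUC) so down-regulated genes score as high as up-regulated
ones.

## Grey relational aggregation

Min–max normalization maps every criterion column exactly onto [0, 1]
(a constant column is an error — it carries no ranking information and the
normalization would divide by zero). All five criteria are declared
larger-is-better; the smaller-is-better generating map is retained for
generality. Δmin and Δmax in the grey relational coefficient are global over
the whole matrix, not per column. The distinguishing coefficient defaults to
α = 0.5; criterion weights default to equal fifths — no principled
inequality between the five criteria presents itself, and both are
configurable. Ties in grade are broken by original gene order (stable sort)
so selection is deterministic. Consequences tested as invariants: grades lie
in (0, 1], a gene maximal on every criterion gets grade exactly 1, and the
ranking is invariant to positive affine transforms of any single criterion
column.

## Gaussian-process classifier

Binary GP classification with a zero-mean prior, squared-exponential kernel
(ARD by default, isotropic available), logistic likelihood and Laplace
inference; EP inference is available with the probit likelihood (EP's
moment-matching steps are closed-form only for probit). Inputs are
standardized per gene with training statistics, which is what makes the
zero-mean prior reasonable. Hyperparameters (log length-scales, log signal
amplitude) start at 0 and maximize the Laplace approximate log marginal
likelihood by L-BFGS-B within [−5, 5]; if optimization fails to improve on
the initial values they are kept and a warning logged. Mode finding uses the
numerically stable B = I + W^{1/2} K W^{1/2} Newton iteration; the kernel
diagonal receives jitter 1e−8·trace/n. Predictive class probabilities
average the likelihood over the latent Gaussian: 64-node Gauss-Hermite for
logistic, the closed form Φ(μ/√(1+σ²)) for probit. On 3-point toys the
Laplace log marginal likelihood is within 0.05 nats and predictive
probabilities within 0.02 of full numerical integration (tested).

## Sparse Poisson LDA

Gene totals ĝⱼ are the raw column sums of the training matrix, and with the
total-count size factors (which sum to 1) this matches the Poisson mean model
exactly; the other size-factor estimates are median-ratio — geometric means
taken only over genes positive in every training sample, to avoid zero
geomeans — and the 75th percentile with linear interpolation between order
statistics. The pseudocount defaults to β = 1 (the original unit-pseudocount
convention; configurable). The soft threshold shrinks |d̂_kj − 1| by exactly
ρ/b without crossing 1. ρ is tuned by internal stratified cross-validation
over a grid of 0 plus 29 log-spaced values reaching the smallest ρ that
shrinks every feature away; accuracy ties resolve to the larger ρ (the
sparser model), and discriminant ties between classes resolve to the lower
class index.

## Evaluation harness

Folds are stratified (plain random folds can go single-class at these sample
sizes). Feature selection, the voom fit and classifier training run inside
the training folds by default; `paper_mode=True` selects genes once on all
samples, a deliberately leaky variant kept for comparison because published
pipelines are often ambiguous on this point. Per repeat, confusion counts
and class-1 probabilities are pooled over the five test folds before
computing metrics. Mutual information is reported in bits as a percentage of
the 1-bit maximum for binary labels. A master seed spawns per-repeat
sub-seeds, so repeats are independent but the whole run is reproducible. The
Mann-Whitney comparison enumerates all rank-sum assignments exactly when the
pooled size is ≤ 12 and otherwise uses the tie-corrected normal
approximation.

## Synthetic data

The generator emulates the features of real count studies the pipeline is
sensitive to: NB overdispersion (var = μ + φμ², default φ = 0.2), baseline
means log-uniform over 1–1000 counts so low and high expressors coexist,
per-sample library sizes varying four-fold (log₂ multipliers in [−1, 1]),
a chosen fraction of DE genes at a fixed |log₂ fold change| with half up- and
half down-regulated (exercising the AUC folding), and an optional
multiplicative batch effect, orthogonal to class by default or confounded on
request. It does **not** emulate gene–gene correlation, outlier samples,
zero-inflation beyond what NB produces, or realistic gene-length effects —
so passing benchmarks here show the pipeline's statistical machinery is
correct and calibrated, not that its real-data performance will match any
particular study.

Benchmark problem sizes used by the test suite and the acceptance script:
null calibration runs 30 independent null datasets of 1000 genes × 40
samples (20 per class) with one stratified 5-fold CV each — independent
replicates are what make a 3-standard-error band around 50% a calibrated
check, since repeated splits of a single finite dataset are strongly
dependent and their standard error understates the dataset-level spread.
Signal recovery uses 20 datasets of 1000 genes with 10 DE genes at
|log₂FC| = 2, φ = 0.2, 40 samples per class, plus one 5-repeat
cross-validation of the full GRA-GP pipeline at the same settings.

## Known limitations

* Binary classification only; the GP and the harness assume two classes.
* The GP optimizes hyperparameters with finite-difference gradients —
  adequate at the small n (tens of samples, ≤ tens of genes) the pipeline
  targets, and the dominant cost in cross-validation.
* sPLDA's probability surrogate for AUC is a softmax over discriminant
  scores; the discriminants themselves are exact, but the surrogate is only
  rank-meaningful.
* The count-table parser expects dense TSV/CSV; very large studies would
  want a sparse path.
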