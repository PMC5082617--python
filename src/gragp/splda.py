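"""Sparse Poisson linear discriminant analysis on raw read counts.

The model assumes X*_j | y*=k ~ Poisson(s* g_j d_kj): g_j is the gene's total
count over the training data, s* a per-sample size factor (total-count,
median-ratio or 75th-percentile quantile estimate), and d_kj a class/gene
ratio profile soft-thresholded toward 1 by a tuning parameter rho.  Genes
whose d_kj equals 1 in every class drop out of the discriminant, so rho
controls how many features are involved in classification.  A test profile
is assigned to the class maximizing

    sum_j X*_j log d_kj  -  s* sum_j g_j d_kj  +  log pi_k ,

with equal priors pi_k = 1/K by default and ties broken toward the lower
class index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gragp.data_io import CountMatrix, LabelVector, ValidationError

SIZE_FACTOR_METHODS = ("total", "median_ratio", "quantile")


@dataclass
class SpldaModel:
    """Fitted sPLDA classifier state."""

    dkj: np.ndarray  # classes x genes
    gj: np.ndarray  # per-gene training totals
    si: np.ndarray  # per-training-sample size factors
    rho: float
    beta: float
    priors: np.ndarray
    size_factor_method: str
    gene_ids: list[str]
    # reference quantities needed to size-factor a test profile
    train_total: float = 0.0
    geomeans: np.ndarray | None = None
    ref_genes: np.ndarray | None = None
    m_sum: float = 0.0
    q_sum: float = 0.0

    def involved_features(self) -> int:
        """Number of genes with d_kj != 1 in at least one class."""
        return int(np.any(self.dkj != 1.0, axis=0).sum())


# ---------------------------------------------------------------- size factors


def size_factors_total(cm: CountMatrix, test_profile: np.ndarray | None = None):
    """Total-count size factors: s_i = X_i. / X.. (training factors sum to 1)."""
    totals = cm.counts.sum(axis=0).astype(float)
    grand = totals.sum()
    if grand <= 0:
        raise ValidationError("training counts are all zero")
    if np.any(totals <= 0):
        raise ValidationError("every training sample needs a positive total count")
    si = totals / grand
    if test_profile is None:
        return si
    s_star = float(np.asarray(test_profile, dtype=float).sum() / grand)
    return si, s_star


def size_factors_median_ratio(cm: CountMatrix, test_profile: np.ndarray | None = None):
    """Median-ratio size factors over genes positive in all training samples.

    m_i = median_j X_ij / geomean_j, normalized to s_i = m_i / sum m_i; a test
    profile uses the training geometric means.
    """
    counts = cm.counts.astype(float)
    ref = np.all(counts > 0, axis=1)
    if not np.any(ref):
        raise ValidationError(
            "median-ratio size factors need at least one gene positive in every "
            "training sample; consider the total-count method"
        )
    geomeans = np.exp(np.log(counts[ref]).mean(axis=1))
    m = np.median(counts[ref] / geomeans[:, None], axis=0)
    if np.any(m <= 0):
        raise ValidationError("non-positive median ratio for a training sample")
    si = m / m.sum()
    if test_profile is None:
        return si
    x = np.asarray(test_profile, dtype=float)
    m_star = float(np.median(x[ref] / geomeans))
    return si, m_star / float(m.sum())


def size_factors_quantile(cm: CountMatrix, test_profile: np.ndarray | None = None, q: float = 75.0):
    """75th-percentile size factors (linear interpolation between order stats)."""
    quantiles = np.percentile(cm.counts, q, axis=0, method="linear")
    if np.any(quantiles <= 0):
        raise ValidationError(f"{q:g}th percentile of a training sample is zero")
    si = quantiles / quantiles.sum()
    if test_profile is None:
        return si
    q_star = float(np.percentile(np.asarray(test_profile, dtype=float), q, method="linear"))
    if q_star <= 0:
        raise ValidationError(f"{q:g}th percentile of the test profile is zero")
    return si, q_star / float(quantiles.sum())


_SIZE_FACTOR_FN = {
    "total": size_factors_total,
    "median_ratio": size_factors_median_ratio,
    "quantile": size_factors_quantile,
}


# -------------------------------------------------------------------- fitting


def soft_threshold_dkj(a: np.ndarray, b: np.ndarray, rho: float) -> np.ndarray:
    """Soft-threshold a/b toward 1: d = a/b -+ rho/b while b|1 - a/b| > rho, else 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ratio = a / b
    d = np.ones_like(ratio)
    up = b * (ratio - 1.0) > rho
    down = b * (1.0 - ratio) > rho
    d[up] = ratio[up] - rho / b[up]
    d[down] = ratio[down] + rho / b[down]
    return d


def estimate_dkj(
    cm: CountMatrix,
    labels: LabelVector,
    si: np.ndarray,
    beta: float = 1.0,
    rho: float = 0.0,
) -> np.ndarray:
    """Class/gene ratio profiles d_kj = soft-threshold of (X_Ckj + beta)/(sum_i si gj + beta)."""
    if beta <= 0:
        raise ValidationError("beta must be positive")
    if rho < 0:
        raise ValidationError("rho must be non-negative")
    counts = cm.counts.astype(float)
    gj = counts.sum(axis=1)
    dkj = np.empty((2, cm.n_genes))
    for k in (0, 1):
        members = labels.labels == k
        a = counts[:, members].sum(axis=1) + beta
        b = si[members].sum() * gj + beta
        dkj[k] = soft_threshold_dkj(a, b, rho)
    return dkj


def splda_fit(
    cm: CountMatrix,
    labels: LabelVector,
    size_factor_method: str = "total",
    rho: float = 0.0,
    beta: float = 1.0,
    priors: np.ndarray | None = None,
) -> SpldaModel:
    """Fit the sPLDA model on training counts and labels."""
    if size_factor_method not in SIZE_FACTOR_METHODS:
        raise ValidationError(f"unknown size-factor method {size_factor_method!r}")
    if labels.n_samples != cm.n_samples:
        raise ValidationError("labels must align with count-matrix samples")
    si = _SIZE_FACTOR_FN[size_factor_method](cm)
    dkj = estimate_dkj(cm, labels, si, beta=beta, rho=rho)
    priors = np.full(2, 0.5) if priors is None else np.asarray(priors, dtype=float)
    if priors.shape != (2,) or abs(priors.sum() - 1.0) > 1e-12 or np.any(priors <= 0):
        raise ValidationError("priors must be two positive numbers summing to 1")
    model = SpldaModel(
        dkj=dkj,
        gj=cm.counts.sum(axis=1).astype(float),
        si=si,
        rho=rho,
        beta=beta,
        priors=priors,
        size_factor_method=size_factor_method,
        gene_ids=list(cm.gene_ids),
        train_total=float(cm.counts.sum()),
    )
    counts = cm.counts.astype(float)
    if size_factor_method == "median_ratio":
        ref = np.all(counts > 0, axis=1)
        model.ref_genes = ref
        model.geomeans = np.exp(np.log(counts[ref]).mean(axis=1))
        m = np.median(counts[ref] / model.geomeans[:, None], axis=0)
        model.m_sum = float(m.sum())
    elif size_factor_method == "quantile":
        model.q_sum = float(np.percentile(counts, 75.0, axis=0, method="linear").sum())
    return model


def test_size_factor(model: SpldaModel, xstar: np.ndarray) -> float:
    """Size factor of a test count profile under the model's method."""
    x = np.asarray(xstar, dtype=float)
    if model.size_factor_method == "total":
        return float(x.sum() / model.train_total)
    if model.size_factor_method == "median_ratio":
        return float(np.median(x[model.ref_genes] / model.geomeans) / model.m_sum)
    return float(np.percentile(x, 75.0, method="linear") / model.q_sum)


def splda_discriminant(model: SpldaModel, xstar: np.ndarray) -> np.ndarray:
    """Per-class discriminant scores for one test count profile."""
    x = np.asarray(xstar, dtype=float)
    if x.shape != (model.dkj.shape[1],):
        raise ValidationError(
            f"test profile has {x.shape} entries; model expects {model.dkj.shape[1]}"
        )
    s_star = test_size_factor(model, x)
    return np.log(model.dkj) @ x - s_star * (model.dkj @ model.gj) + np.log(model.priors)


def splda_classify(model: SpldaModel, xstar: np.ndarray):
    """Assign a test profile to the class with the largest discriminant score.

    Returns (label, scores); exact ties go to the lower class index.
    """
    scores = splda_discriminant(model, xstar)
    return int(np.argmax(scores)), scores


def splda_predict(model: SpldaModel, counts_star: np.ndarray) -> np.ndarray:
    """Classify each column of a genes x samples test count matrix."""
    counts_star = np.atleast_2d(np.asarray(counts_star, dtype=float))
    return np.array([splda_classify(model, counts_star[:, i])[0] for i in range(counts_star.shape[1])])


def rho_grid_max(cm: CountMatrix, labels: LabelVector, size_factor_method: str, beta: float) -> float:
    """Smallest rho that shrinks every d_kj to 1 on the full training data."""
    si = _SIZE_FACTOR_FN[size_factor_method](cm)
    counts = cm.counts.astype(float)
    gj = counts.sum(axis=1)
    worst = 0.0
    for k in (0, 1):
        members = labels.labels == k
        a = counts[:, members].sum(axis=1) + beta
        b = si[members].sum() * gj + beta
        worst = max(worst, float(np.max(b * np.abs(1.0 - a / b))))
    return worst


def default_rho_grid(
    cm: CountMatrix, labels: LabelVector, size_factor_method: str = "total", beta: float = 1.0, n: int = 30
) -> np.ndarray:
    """0 plus log-spaced values up to the full-shrinkage rho."""
    top = rho_grid_max(cm, labels, size_factor_method, beta)
    if top <= 0:
        return np.zeros(1)
    return np.concatenate([[0.0], np.geomspace(max(top * 1e-4, 1e-12), top, n - 1)])


def splda_tune_rho(
    cm: CountMatrix,
    labels: LabelVector,
    grid: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
    size_factor_method: str = "total",
    beta: float = 1.0,
):
    """Choose rho by internal stratified cross-validation.

    Returns (best_rho, per-rho CV accuracy, per-rho involved-feature count on
    the full data).  Accuracy ties resolve to the larger rho (sparser model).
    """
    from sklearn.model_selection import StratifiedKFold

    if grid is None:
        grid = default_rho_grid(cm, labels, size_factor_method, beta)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("rho grid must be non-empty")
    class_sizes = np.bincount(labels.labels, minlength=2)
    if np.any(class_sizes < folds):
        raise ValidationError(f"{folds}-fold CV infeasible for class sizes {class_sizes.tolist()}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = np.zeros(grid.size)
    for train_idx, test_idx in skf.split(np.zeros(labels.n_samples), labels.labels):
        cm_tr = cm.subset_samples(train_idx)
        y_tr = labels.subset(train_idx)
        for r, rho in enumerate(grid):
            model = splda_fit(cm_tr, y_tr, size_factor_method, rho=rho, beta=beta)
            pred = splda_predict(model, cm.counts[:, test_idx])
            correct[r] += int(np.sum(pred == labels.labels[test_idx]))
    accuracy = correct / labels.n_samples

    involved = np.empty(grid.size, dtype=int)
    for r, rho in enumerate(grid):
        involved[r] = splda_fit(cm, labels, size_factor_method, rho=rho, beta=beta).involved_features()

    best = np.flatnonzero(accuracy == accuracy.max())
    best_rho = float(grid[best][np.argmax(grid[best])])
    return best_rho, accuracy, involved
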