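"""Repeated stratified 5-fold cross-validation, metrics, and rank-sum comparison.

Each repeat draws a fresh stratified 5-fold partition; within every fold the
whole pipeline — voom transformation, filter scoring, grey relational top-k
selection, classifier training — runs on the training folds only, so no test
information leaks into feature selection (``paper_mode=True`` instead selects
genes once on all samples before cross-validation).  Per repeat, confusion
counts and class-1 probabilities are pooled over the five test folds and
summarized as accuracy, F-measure, AUC and mutual information, all reported
in percent.  Result sets from two methods are compared with a two-sided
Mann-Whitney rank-sum test (exact enumeration for small samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.model_selection import StratifiedKFold

from gragp.data_io import CountMatrix, LabelVector, ValidationError
from gragp.gp import GPConfig, gp_predict, gp_train
from gragp.gra import GreyConfig, select_top_k
from gragp.scores import raw_auc, score_all
from gragp.splda import splda_fit, splda_predict
from gragp.voom import log_cpm, voom

N_FOLDS = 5


@dataclass
class CVResult:
    """Per-repeat percentage metrics with mean and standard error."""

    metrics: dict[str, np.ndarray]  # metric name -> per-repeat values, in %
    n_repeats: int
    seed: int
    config: dict = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return float(np.mean(self.metrics[name]))

    def stderr(self, name: str) -> float:
        vals = self.metrics[name]
        return float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (self.mean(m), self.stderr(m)) for m in self.metrics}


# -------------------------------------------------------------------- metrics


def confusion_metrics(y_true, y_pred, positive: int = 1):
    """Accuracy, precision, recall and F-measure on the unit scale."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    tp = np.sum((y_pred == positive) & (y_true == positive))
    fp = np.sum((y_pred == positive) & (y_true != positive))
    fn = np.sum((y_pred != positive) & (y_true == positive))
    accuracy = float(np.mean(y_pred == y_true))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = 2.0 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return accuracy, float(precision), float(recall), float(f)


def mutual_information(y_true, y_pred):
    """MI between predicted and true binary labels, in bits (and as % of 1 bit).

    Computed on the empirical joint distribution with the 0*log0 := 0
    convention; symmetric under relabeling either argument.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    n = y_true.size
    mi = 0.0
    for c_hat in (0, 1):
        p_hat = np.mean(y_pred == c_hat)
        for c in (0, 1):
            joint = np.sum((y_pred == c_hat) & (y_true == c)) / n
            p_c = np.mean(y_true == c)
            if joint > 0:
                mi += joint * np.log2(joint / (p_hat * p_c))
    return float(mi), float(100.0 * mi)


def classifier_auc(y_true, prob) -> float:
    """Empirical AUC of class-1 probabilities against binary truth (ties half)."""
    y_true = np.asarray(y_true)
    prob = np.asarray(prob, dtype=float)
    if np.any((prob < 0) | (prob > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    if len(set(np.unique(y_true).tolist())) < 2:
        raise ValidationError("AUC undefined for one-class truth")
    return raw_auc(prob[y_true == 0], prob[y_true == 1])


# ------------------------------------------------------------ Mann-Whitney U


def mann_whitney_compare(a, b) -> float:
    """Two-sided rank-sum p-value for equal location of two result sets.

    Exact enumeration of all rank-sum assignments when len(a)+len(b) <= 12
    (ties handled through midranks); otherwise the normal approximation with
    tie-corrected variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each result set needs at least two values")
    pooled = np.concatenate([a, b])
    n1, n = a.size, a.size + b.size
    ranks = rankdata(pooled, method="average")
    w_obs = ranks[:n1].sum()
    expect = n1 * (n + 1) / 2.0

    if n <= 12:
        dev = abs(w_obs - expect)
        hits = sum(
            1
            for idx in combinations(range(n), n1)
            if abs(ranks[list(idx)].sum() - expect) >= dev - 1e-9
        )
        return hits / comb(n, n1)

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * (n - n1) / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (w_obs - expect) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


# ------------------------------------------------------------ cross-validation


def _gp_fold(cm, labels, train_idx, test_idx, k, grey_cfg, gp_cfg, batch, paper_genes):
    """Train GRA-GP on the training folds, predict the test fold."""
    cm_tr = cm.subset_samples(train_idx)
    y_tr = labels.subset(train_idx)
    batch_tr = [batch[i] for i in train_idx] if batch is not None else None
    if paper_genes is None:
        tm = voom(cm_tr, y_tr, batch=batch_tr)
        table = score_all(tm, y_tr)
        _, genes = select_top_k(table, grey_cfg, k)
        values_tr = tm.subset_genes(genes).values
    else:
        genes = paper_genes
        tm = voom(cm_tr, y_tr, batch=batch_tr)
        values_tr = tm.subset_genes(genes).values
    model = gp_train(values_tr.T, y_tr, gp_cfg)

    cm_te = cm.subset_samples(test_idx)
    gene_rows = [cm.gene_ids.index(g) for g in genes]
    values_te = log_cpm(cm_te)[gene_rows, :]
    prob = gp_predict(model, values_te.T)
    return prob, (prob > 0.5).astype(int)


def _splda_fold(cm, labels, train_idx, test_idx, size_factor_method, rho, beta):
    cm_tr = cm.subset_samples(train_idx)
    y_tr = labels.subset(train_idx)
    model = splda_fit(cm_tr, y_tr, size_factor_method, rho=rho, beta=beta)
    pred = splda_predict(model, cm.counts[:, test_idx])
    # probability surrogate from softmax of discriminant scores for AUC
    from gragp.splda import splda_discriminant

    prob = np.empty(len(test_idx))
    for j, i in enumerate(test_idx):
        s = splda_discriminant(model, cm.counts[:, i].astype(float))
        s = s - s.max()
        e = np.exp(s)
        prob[j] = e[1] / e.sum()
    return prob, pred


def cross_validate(
    cm: CountMatrix,
    labels: LabelVector,
    classifier: str = "gp",
    k: int = 10,
    n_repeats: int = 30,
    seed: int = 0,
    grey_cfg: GreyConfig | None = None,
    gp_cfg: GPConfig | None = None,
    size_factor_method: str = "total",
    rho: float = 0.0,
    beta: float = 1.0,
    batch=None,
    paper_mode: bool = False,
) -> CVResult:
    """Repeated stratified 5-fold CV of the full pipeline.

    ``classifier`` is "gp" (GRA top-k + GP on log-CPM values) or "splda"
    (sPLDA on raw counts).  With ``paper_mode=True`` the GRA gene subset is
    selected once on all samples before the folds are drawn.
    """
    if labels.n_samples != cm.n_samples:
        raise ValidationError("labels must align with count-matrix samples")
    class_sizes = np.bincount(labels.labels, minlength=2)
    if np.any(class_sizes < N_FOLDS):
        raise ValidationError(
            f"each class needs >= {N_FOLDS} samples for stratified {N_FOLDS}-fold CV"
        )
    if batch is None:
        batch = cm.batch
    gp_cfg = gp_cfg or GPConfig()

    paper_genes = None
    if paper_mode and classifier == "gp":
        tm_all = voom(cm, labels, batch=batch)
        _, paper_genes = select_top_k(score_all(tm_all, labels), grey_cfg, k)

    rng = np.random.default_rng(seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)

    names = ("accuracy", "f_measure", "auc", "mi")
    values = {m: np.empty(n_repeats) for m in names}
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=int(repeat_seeds[r]))
        y_true = np.empty(labels.n_samples, dtype=int)
        y_pred = np.empty(labels.n_samples, dtype=int)
        prob = np.empty(labels.n_samples)
        for train_idx, test_idx in skf.split(np.zeros(labels.n_samples), labels.labels):
            if classifier == "gp":
                p, yhat = _gp_fold(
                    cm, labels, train_idx, test_idx, k, grey_cfg, gp_cfg, batch, paper_genes
                )
            elif classifier == "splda":
                p, yhat = _splda_fold(
                    cm, labels, train_idx, test_idx, size_factor_method, rho, beta
                )
            elif callable(classifier):
                p, yhat = classifier(cm, labels, train_idx, test_idx)
            else:
                raise ValidationError(f"unknown classifier {classifier!r}")
            y_true[test_idx] = labels.labels[test_idx]
            y_pred[test_idx] = yhat
            prob[test_idx] = p
        acc, _, _, f = confusion_metrics(y_true, y_pred)
        _, mi_pct = mutual_information(y_true, y_pred)
        values["accuracy"][r] = 100.0 * acc
        values["f_measure"][r] = 100.0 * f
        values["auc"][r] = 100.0 * classifier_auc(y_true, prob)
        values["mi"][r] = mi_pct

    return CVResult(
        metrics=values,
        n_repeats=n_repeats,
        seed=seed,
        config={
            "classifier": classifier if isinstance(classifier, str) else "custom",
            "k": k,
            "paper_mode": paper_mode,
            "size_factor_method": size_factor_method,
            "rho": rho,
        },
    )
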