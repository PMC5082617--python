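"""Five filter statistics that score each gene's discrimination of two classes.

Every score is a non-negative magnitude — larger means more discriminative —
computed on transformed (log2-CPM) expression values split by class:

* absolute two-sample t statistic (Welch denominator),
* symmetric Kullback-Leibler (entropy) divergence between class Gaussians,
* Bhattacharyya distance between class Gaussians,
* absolute standardized Wilcoxon rank-sum statistic (midranks, tie-corrected
  variance, rank sum taken over the smaller group),
* empirical ROC AUC folded as max(AUC, 1-AUC) so down-regulation scores as
  high as up-regulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from gragp.data_io import LabelVector, ValidationError
from gragp.voom import TransformedMatrix

CRITERIA = ("t", "entropy", "bhattacharyya", "wilcoxon", "auc")

#: variance floor applied when a class is constant (entropy / Bhattacharyya)
VAR_FLOOR = 1e-8
#: cap for the t score when the pooled variance is zero but means differ
T_CAP = 1e8


@dataclass
class ClassSummary:
    """First- and second-moment summary of one gene's values in two classes."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValidationError("each class needs at least two samples")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValidationError("standard deviations must be non-negative")

    @classmethod
    def from_samples(cls, x1: np.ndarray, x2: np.ndarray) -> "ClassSummary":
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        return cls(
            mu1=float(np.mean(x1)),
            mu2=float(np.mean(x2)),
            sigma1=float(np.std(x1, ddof=1)),
            sigma2=float(np.std(x2, ddof=1)),
            n1=x1.size,
            n2=x2.size,
        )


@dataclass
class ScoreTable:
    """Genes x 5 matrix of non-negative criterion scores.

    Column order is fixed: (t, entropy, bhattacharyya, wilcoxon, auc).
    """

    scores: np.ndarray
    gene_ids: list[str]
    criteria: tuple[str, ...] = CRITERIA

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(self.criteria):
            raise ValidationError(f"scores must be genes x {len(self.criteria)}")
        if self.scores.shape[0] != len(self.gene_ids):
            raise ValidationError("scores rows must match gene IDs")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("scores must be finite")
        if np.any(self.scores < 0):
            raise ValidationError("scores must be non-negative")


def t_score(s: ClassSummary) -> float:
    """|t| with the Welch denominator; capped when the pooled variance vanishes."""
    denom_sq = s.sigma1**2 / s.n1 + s.sigma2**2 / s.n2
    diff = s.mu1 - s.mu2
    if denom_sq == 0.0:
        return 0.0 if diff == 0.0 else T_CAP
    return abs(diff) / np.sqrt(denom_sq)


def entropy_score(s: ClassSummary) -> float:
    """Symmetric KL divergence between the two class Gaussians."""
    v1 = max(s.sigma1**2, VAR_FLOOR)
    v2 = max(s.sigma2**2, VAR_FLOOR)
    diff_sq = (s.mu1 - s.mu2) ** 2
    return 0.5 * (v1 / v2 + v2 / v1 - 2.0 + (1.0 / v1 + 1.0 / v2) * diff_sq)


def bhattacharyya_score(s: ClassSummary) -> float:
    """Bhattacharyya distance between the two class Gaussians."""
    v1 = max(s.sigma1**2, VAR_FLOOR)
    v2 = max(s.sigma2**2, VAR_FLOOR)
    diff_sq = (s.mu1 - s.mu2) ** 2
    return 0.25 * np.log(0.25 * (v1 / v2 + v2 / v1 + 2.0)) + 0.25 * diff_sq / (v1 + v2)


def wilcoxon_score(x1: np.ndarray, x2: np.ndarray) -> float:
    """Absolute standardized rank sum of the smaller group.

    W is the midrank sum of the smaller group over the pooled sample;
    the score is |W - E[W]| / sd[W] with the tie-corrected variance.  When the
    pooled values are all identical the score is 0.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValidationError("each class needs at least two samples")
    if x2.size < x1.size:
        x1, x2 = x2, x1
    ns, no = x1.size, x2.size
    n = ns + no
    pooled = np.concatenate([x1, x2])
    ranks = rankdata(pooled, method="average")
    w = ranks[:ns].sum()
    expect = ns * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = ns * no / 12.0 * (n + 1 - tie_term)
    if var <= 0.0:
        return 0.0
    return abs(w - expect) / np.sqrt(var)


def auc_score(x1: np.ndarray, x2: np.ndarray) -> float:
    """Folded empirical AUC: max(AUC, 1-AUC), ties counted half."""
    raw = raw_auc(x1, x2)
    return max(raw, 1.0 - raw)


def raw_auc(x1: np.ndarray, x2: np.ndarray) -> float:
    """Empirical P(X2 > X1) + 0.5 P(X2 = X1) via the rank (Mann-Whitney) identity."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 1 or n2 < 1:
        raise ValidationError("each class needs at least one sample")
    ranks = rankdata(np.concatenate([x1, x2]), method="average")
    r2 = ranks[n1:].sum()
    u2 = r2 - n2 * (n2 + 1) / 2.0  # number of (x1, x2) pairs with x2 > x1, ties half
    return u2 / (n1 * n2)


def score_all(tm: TransformedMatrix, labels: LabelVector) -> ScoreTable:
    """Score every gene with the five criteria on its class-split values."""
    if labels.n_samples != len(tm.sample_ids):
        raise ValidationError("labels must align with transformed samples")
    mask1 = labels.labels == 0
    mask2 = labels.labels == 1
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValidationError("each class needs at least two samples")
    v1 = tm.values[:, mask1]
    v2 = tm.values[:, mask2]
    n_genes = tm.values.shape[0]
    out = np.empty((n_genes, 5), dtype=float)

    # moment-based scores, vectorized over genes
    mu1, mu2 = v1.mean(axis=1), v2.mean(axis=1)
    s1 = v1.std(axis=1, ddof=1)
    s2 = v2.std(axis=1, ddof=1)
    var1 = np.maximum(s1**2, VAR_FLOOR)
    var2 = np.maximum(s2**2, VAR_FLOOR)
    diff = mu1 - mu2
    denom_sq = s1**2 / v1.shape[1] + s2**2 / v2.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(diff) / np.sqrt(denom_sq)
    t = np.where(denom_sq == 0.0, np.where(diff == 0.0, 0.0, T_CAP), t)
    out[:, 0] = t
    out[:, 1] = 0.5 * (var1 / var2 + var2 / var1 - 2.0 + (1.0 / var1 + 1.0 / var2) * diff**2)
    out[:, 2] = 0.25 * np.log(0.25 * (var1 / var2 + var2 / var1 + 2.0)) + 0.25 * diff**2 / (
        var1 + var2
    )

    # rank-based scores, per gene
    for g in range(n_genes):
        out[g, 3] = wilcoxon_score(v1[g], v2[g])
        out[g, 4] = auc_score(v1[g], v2[g])

    table = ScoreTable(out, list(tm.gene_ids))
    for j, name in enumerate(table.criteria):
        col = table.scores[:, j]
        if n_genes > 1 and np.all(col == col[0]):
            raise ValidationError(
                f"criterion {name!r} is constant across genes; "
                "grey relational normalization would degenerate"
            )
    return table
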