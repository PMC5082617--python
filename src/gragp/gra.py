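"""Grey relational analysis: aggregate five criterion scores into one grade.

Genes play the role of alternatives in a multi-criteria decision problem and
the five filter scores are the criteria.  Each criterion column is min-max
normalized to [0,1] (the comparability sequence), compared against the ideal
all-ones reference sequence through the grey relational coefficient

    delta_ij = (Dmin + alpha * Dmax) / (|1 - x_ij| + alpha * Dmax),

with Dmin/Dmax the global extremes of |1 - x_ij|, and the weighted mean of a
gene's five coefficients is its grey relational grade.  Genes are ranked by
descending grade and the top-k selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gragp.data_io import ValidationError
from gragp.scores import ScoreTable

LARGER_BETTER = "larger-better"
SMALLER_BETTER = "smaller-better"


@dataclass
class GreyConfig:
    """Distinguishing coefficient, criterion weights and per-criterion direction.

    All five filter scores are magnitudes where larger means more
    discriminative, so the default direction is larger-better throughout.
    """

    alpha: float = 0.5
    weights: np.ndarray = field(default_factory=lambda: np.full(5, 0.2))
    directions: tuple[str, ...] = (LARGER_BETTER,) * 5

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValidationError("weights must be non-negative and sum to 1")
        bad = set(self.directions) - {LARGER_BETTER, SMALLER_BETTER}
        if bad:
            raise ValidationError(f"unknown directions: {bad}")


@dataclass
class GreyResult:
    """Per-gene grey relational grades, the induced ranking, and the
    comparability matrix the grades were computed from."""

    grades: np.ndarray
    ranks: np.ndarray  # gene indices ordered by descending grade, stable ties
    normalized: np.ndarray
    gene_ids: list[str]

    def top_genes(self, k: int) -> list[str]:
        return [self.gene_ids[i] for i in self.ranks[:k]]


def grey_generate(scores: np.ndarray, directions) -> np.ndarray:
    """Min-max normalize each criterion column onto [0,1] (comparability matrix).

    Larger-better columns map y -> (y - min)/(max - min); smaller-better
    columns map y -> (max - y)/(max - min).  A constant column has no range
    and raises.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValidationError("scores must be a 2-D matrix")
    if len(directions) != scores.shape[1]:
        raise ValidationError("one direction required per criterion")
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    span = hi - lo
    constant = span == 0.0
    if np.any(constant):
        raise ValidationError(
            f"criterion column(s) {np.flatnonzero(constant).tolist()} are constant; "
            "min-max normalization is undefined"
        )
    x = (scores - lo) / span
    for j, d in enumerate(directions):
        if d == SMALLER_BETTER:
            x[:, j] = 1.0 - x[:, j]
    return x


def grey_coefficient(x: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Grey relational coefficient of every cell against the all-ones reference."""
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
        raise ValidationError("comparability values must lie in [0, 1]")
    delta = np.abs(1.0 - x)
    dmin = delta.min()
    dmax = delta.max()
    if dmax == 0.0:
        return np.ones_like(delta)
    return (dmin + alpha * dmax) / (delta + alpha * dmax)


def grey_grade(coeffs: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted mean of each gene's coefficients: the grey relational grade."""
    coeffs = np.asarray(coeffs, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (coeffs.shape[1],):
        raise ValidationError("one weight required per criterion")
    if abs(weights.sum() - 1.0) > 1e-12:
        raise ValidationError("weights must sum to 1")
    return coeffs @ weights


def grey_relational_grades(scores: ScoreTable, cfg: GreyConfig | None = None) -> GreyResult:
    """Run the full grey relational pipeline on a score table."""
    cfg = cfg or GreyConfig()
    x = grey_generate(scores.scores, cfg.directions)
    coeffs = grey_coefficient(x, cfg.alpha)
    grades = grey_grade(coeffs, cfg.weights)
    ranks = np.argsort(-grades, kind="stable")
    return GreyResult(grades, ranks, x, list(scores.gene_ids))


def select_top_k(
    scores: ScoreTable, cfg: GreyConfig | None = None, k: int = 10
) -> tuple[GreyResult, list[str]]:
    """Select the k genes with the highest grey relational grades.

    Ties in grade are broken by original gene order (stable sort), making the
    selection deterministic for identical inputs.
    """
    n = scores.scores.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k must lie in [1, {n}], got {k}")
    result = grey_relational_grades(scores, cfg)
    return result, result.top_genes(k)
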