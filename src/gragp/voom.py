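"""Log-CPM transformation with mean-variance precision weights.

Counts are converted to log2 counts-per-million with a small offset, a per-gene
linear model is fitted on a sample-level design (intercept + class + optional
batch), and a lowess smoother of sqrt residual standard deviation against mean
log2 count yields a mean-variance trend.  Each observation's predicted
log2-count is pushed through the trend and the result raised to the -4th power
gives an inverse-variance precision weight, so downstream normal-based
statistics can treat the transformed values like microarray intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from gragp.data_io import CountMatrix, LabelVector, ValidationError

#: count offset added per cell; the library-size offset is twice this value
DEFAULT_OFFSET = 0.5
#: lowess span for the mean-variance trend
TREND_SPAN = 0.5
#: floor for sqrt residual sd of degenerate (zero-variance) genes
SQRT_SD_FLOOR = 1e-6


@dataclass
class TransformedMatrix:
    """Continuous log2-CPM values plus per-observation precision weights.

    ``values`` and ``weights`` are genes x samples; ``design`` is the
    samples x covariates matrix used when fitting residual variances.
    """

    values: np.ndarray
    weights: np.ndarray
    design: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("transformed values must be finite")
        if not (np.all(np.isfinite(self.weights)) and np.all(self.weights > 0)):
            raise ValidationError("precision weights must be positive and finite")

    def subset_genes(self, gene_ids) -> "TransformedMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return TransformedMatrix(
            self.values[rows, :],
            self.weights[rows, :],
            self.design,
            list(gene_ids),
            list(self.sample_ids),
        )


def log_cpm(cm: CountMatrix, offset: float = DEFAULT_OFFSET) -> np.ndarray:
    """log2 counts-per-million: log2((count+offset)/(libsize+2*offset) * 1e6)."""
    if offset <= 0:
        raise ValueError("offset must be positive")
    lib = cm.library_sizes().astype(float)
    if np.any(lib <= 0):
        raise ValidationError("every sample must have a positive library size")
    return np.log2((cm.counts + offset) / (lib[None, :] + 2 * offset) * 1e6)


def build_design(labels: LabelVector, batch=None) -> np.ndarray:
    """Intercept + class indicator + one indicator per extra batch level."""
    n = labels.n_samples
    cols = [np.ones(n), labels.labels.astype(float)]
    if batch is not None:
        if len(batch) != n:
            raise ValidationError("batch labels must align with samples")
        levels = sorted(set(batch))
        for level in levels[1:]:  # first level absorbed by the intercept
            cols.append(np.array([1.0 if b == level else 0.0 for b in batch]))
    return np.column_stack(cols)


def fit_mean_variance_trend(
    values: np.ndarray, design: np.ndarray, span: float = TREND_SPAN, x_offset: float = 0.0
):
    """Fit the lowess mean-variance trend of a per-gene linear model.

    Regresses every gene's values on the shared design, collects per-gene
    (mean log2 count, sqrt residual sd) points, smooths them with lowess and
    returns ``(trend, fitted)`` where ``trend`` maps mean log2 count to a
    predicted sqrt standard deviation (flat extrapolation beyond the data
    range) and ``fitted`` is the genes x samples matrix of fitted values.
    ``x_offset`` shifts the per-gene mean of ``values`` onto the trend's x
    scale (log2-CPM inputs use the average log2 library-size offset).
    """
    n_genes, n_samples = values.shape
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    if n_samples <= rank:
        raise ValidationError("need more samples than design parameters")
    if n_genes < 10:
        raise ValidationError("need at least 10 genes to fit a mean-variance trend")
    coef, *_ = np.linalg.lstsq(design, values.T, rcond=None)
    fitted = (design @ coef).T
    resid = values - fitted
    df_resid = n_samples - rank
    sigma = np.sqrt((resid**2).sum(axis=1) / df_resid)
    sqrt_sd = np.maximum(np.sqrt(sigma), SQRT_SD_FLOOR)
    mean_log_value = values.mean(axis=1) + x_offset

    smoothed = sm.nonparametric.lowess(
        sqrt_sd, mean_log_value, frac=span, it=3, return_sorted=True
    )
    xs, ys = smoothed[:, 0], smoothed[:, 1]
    # dedupe x for interpolation; lowess output is sorted in x
    xs, first = np.unique(xs, return_index=True)
    ys = ys[first]

    def trend(x: np.ndarray) -> np.ndarray:
        # flat extrapolation keeps predicted sd positive outside the range
        y = np.interp(np.asarray(x, dtype=float), xs, ys)
        return np.maximum(y, SQRT_SD_FLOOR)

    return trend, fitted


def voom(
    cm: CountMatrix,
    labels: LabelVector,
    batch=None,
    offset: float = DEFAULT_OFFSET,
    remove_batch: bool = False,
    span: float = TREND_SPAN,
) -> TransformedMatrix:
    """Transform counts to log2-CPM values with precision weights.

    The design holds intercept, class indicator and (when given) batch
    indicators; the batch covariate then enters the residual variances and the
    weights.  With ``remove_batch=True`` the fitted batch contribution is also
    subtracted from the returned values.
    """
    if labels.n_samples != cm.n_samples:
        raise ValidationError("labels must align with count-matrix samples")
    if batch is None and cm.batch is not None:
        batch = cm.batch
    values = log_cpm(cm, offset=offset)
    design = build_design(labels, batch)
    lib = cm.library_sizes().astype(float) + 2 * offset
    x_offset = float(np.mean(np.log2(lib)) - np.log2(1e6))
    trend, fitted = fit_mean_variance_trend(values, design, span=span, x_offset=x_offset)

    # predicted log2 count for each observation, on the trend's x scale
    fitted_log_count = fitted + np.log2(lib)[None, :] - np.log2(1e6)
    weights = trend(fitted_log_count) ** (-4.0)

    if remove_batch and batch is not None:
        coef, *_ = np.linalg.lstsq(design, values.T, rcond=None)
        batch_cols = np.arange(2, design.shape[1])
        values = values - (design[:, batch_cols] @ coef[batch_cols, :]).T

    return TransformedMatrix(values, weights, design, list(cm.gene_ids), list(cm.sample_ids))
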