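"""Negative-binomial count simulation with planted differential expression.

Counts are drawn from NB(mean = L_s * mu_g * FC^(class * DE_g) * B^batch,
variance = mean + phi * mean^2): baseline gene means mu_g are log-uniform so
low and high expressors coexist, per-sample library-size multipliers L_s vary
log-uniformly, a chosen fraction of genes is differentially expressed at a
fixed log2 fold change (half up-, half down-regulated in class 1), and an
optional multiplicative batch effect can be applied orthogonally to class or
confounded with it.  phi = 0 degenerates to Poisson sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gragp.data_io import CountMatrix, LabelVector, ValidationError


@dataclass
class SimConfig:
    """Generator settings; defaults give a small two-class overdispersed study."""

    n_genes: int = 1000
    n_per_class: tuple[int, int] = (40, 40)
    de_fraction: float = 0.01
    log2_fold_change: float = 2.0
    dispersion: float = 0.2  # phi in var = mu + phi mu^2; 0 -> Poisson
    baseline_mean_log_range: tuple[float, float] = (0.0, 3.0)  # log10 of mean counts
    libsize_log_range: tuple[float, float] = (-1.0, 1.0)  # log2 multiplier range
    batch_effect_log2: float | None = None
    batch_confounded: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or min(self.n_per_class) < 1:
            raise ValidationError("need at least one gene and one sample per class")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValidationError("de_fraction must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be non-negative")


@dataclass
class SimTruth:
    """Ground truth of a simulated study."""

    de_gene_ids: set[str]
    up_gene_ids: set[str]
    class_means: np.ndarray  # genes x 2 expected per-class base means
    libsize_multipliers: np.ndarray
    batch: list[str] | None = None


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion phi (var = mu + phi mu^2)."""
    if phi == 0.0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, LabelVector, SimTruth]:
    """Generate a count matrix, class labels, and the planted ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n1, n2 = cfg.n_per_class
    n = n1 + n2
    labels = np.array([0] * n1 + [1] * n2)

    lo, hi = cfg.baseline_mean_log_range
    mu = 10.0 ** rng.uniform(lo, hi, size=cfg.n_genes)
    lib = 2.0 ** rng.uniform(*cfg.libsize_log_range, size=n)

    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    up = de_idx[: n_de // 2 + n_de % 2]  # half up-, half down-regulated
    down = de_idx[n_de // 2 + n_de % 2 :]
    log2fc = np.zeros(cfg.n_genes)
    log2fc[up] = cfg.log2_fold_change
    log2fc[down] = -cfg.log2_fold_change

    mean = mu[:, None] * np.ones((1, n))
    mean[:, labels == 1] *= (2.0 ** log2fc)[:, None]

    batch = None
    if cfg.batch_effect_log2 is not None:
        if cfg.batch_confounded:
            in_b = labels == 1
        else:
            in_b = np.arange(n) % 2 == 1  # alternating: orthogonal to class
        batch = ["b2" if flag else "b1" for flag in in_b]
        mean[:, in_b] *= 2.0**cfg.batch_effect_log2

    mean = mean * lib[None, :]
    counts = _nb_sample(rng, mean, cfg.dispersion)

    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    sample_ids = [f"s{i:03d}" for i in range(n)]
    cm = CountMatrix(counts.astype(np.int64), gene_ids, sample_ids, batch)
    lv = LabelVector(labels, ("class0", "class1"))
    class_means = np.column_stack([mu, mu * 2.0**log2fc])
    truth = SimTruth(
        de_gene_ids={gene_ids[i] for i in de_idx},
        up_gene_ids={gene_ids[i] for i in up},
        class_means=class_means,
        libsize_multipliers=lib,
        batch=batch,
    )
    return cm, lv, truth


def recovery_report(selected, truth: SimTruth) -> dict[str, float]:
    """Precision and recall of a selected gene set against the planted DE set."""
    selected = set(selected)
    de = truth.de_gene_ids
    hits = len(selected & de)
    out = {
        "n_selected": float(len(selected)),
        "n_de": float(len(de)),
        "n_recovered": float(hits),
        "recall": hits / len(de) if de else 0.0,
    }
    if selected:
        out["precision"] = hits / len(selected)
        out["empty_selection"] = 0.0
    else:
        out["precision"] = 0.0
        out["empty_selection"] = 1.0
    return out
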