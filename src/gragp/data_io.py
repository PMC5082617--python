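"""Reading, writing and validation of count matrices and sample labels.

Count tables are genes-in-rows, samples-in-columns: the first column holds gene
IDs, the header row holds sample IDs, and every cell is a non-negative integer
read count.  Labels are two-column tables (sample_id, class) with exactly two
classes.  Missing values are rejected rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file cannot be parsed into the expected layout."""


class ValidationError(ValueError):
    """Raised when parsed data violate a contract (negative counts, duplicate IDs...)."""


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    counts : ndarray of int, shape (n_genes, n_samples)
    gene_ids : sequence of unique str
    sample_ids : sequence of unique str
    batch : optional per-sample categorical labels (aligned to ``sample_ids``)
    """

    counts: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    batch: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_float = np.asarray(self.counts, dtype=float)
            if not np.all(np.isfinite(as_float)):
                raise ValidationError("counts contain NaN or infinite values")
            if not np.all(as_float == np.floor(as_float)):
                raise ValidationError("counts must be integers")
            self.counts = as_float.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} gene IDs x {len(self.sample_ids)} sample IDs"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene IDs must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample IDs must be unique")
        if self.batch is not None:
            self.batch = [str(b) for b in self.batch]
            if len(self.batch) != len(self.sample_ids):
                raise ValidationError("batch labels must align with samples")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Per-sample total read count (column sums)."""
        return self.counts.sum(axis=0)

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        """Return a new matrix restricted to ``gene_ids``, in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            rows = [index[g] for g in gene_ids]
        except KeyError as exc:
            raise ValidationError(f"unknown gene ID {exc.args[0]!r}") from exc
        return CountMatrix(self.counts[rows, :], list(gene_ids), list(self.sample_ids), self.batch)

    def subset_samples(self, idx: Sequence[int]) -> "CountMatrix":
        idx = list(idx)
        return CountMatrix(
            self.counts[:, idx],
            list(self.gene_ids),
            [self.sample_ids[i] for i in idx],
            [self.batch[i] for i in idx] if self.batch is not None else None,
        )


@dataclass
class LabelVector:
    """Binary class labels aligned to a count matrix's sample order.

    ``labels`` holds 0/1 codes; ``class_names`` maps code -> original name.
    """

    labels: np.ndarray
    class_names: tuple[str, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be one-dimensional")
        present = set(np.unique(self.labels).tolist())
        if not present <= {0, 1}:
            raise ValidationError("labels must be coded 0/1")
        if present != {0, 1}:
            raise ValidationError("both classes must be present")

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    def subset(self, idx: Sequence[int]) -> "LabelVector":
        return LabelVector(self.labels[list(idx)], self.class_names)


_DIALECT_SEP = {"tsv": "\t", "csv": ","}


def read_count_matrix(path: str | Path, dialect: str = "tsv") -> CountMatrix:
    """Read a count table (first column gene IDs, header sample IDs).

    Raises :class:`FormatError` for malformed layout and :class:`ValidationError`
    for negative, missing or non-integer cells and duplicate IDs.
    """
    sep = _sep_for(dialect)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse count table {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"count table {path} has no sample columns")
    if df.isna().any().any():
        raise ValidationError(f"count table {path} contains missing values")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"count table {path} contains non-numeric cells")
    return CountMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))


def write_count_matrix(cm: CountMatrix, path: str | Path, dialect: str = "tsv") -> None:
    """Write a count matrix in the layout :func:`read_count_matrix` expects."""
    sep = _sep_for(dialect)
    df = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids)
    df.to_csv(path, sep=sep, index_label="gene_id")


def filter_zero_genes(cm: CountMatrix) -> CountMatrix:
    """Drop genes whose count is zero in every sample; preserve gene order."""
    keep = np.flatnonzero(cm.counts.sum(axis=1) > 0)
    if keep.size == 0:
        raise ValidationError("all genes have zero counts in every sample")
    return CountMatrix(
        cm.counts[keep, :], [cm.gene_ids[i] for i in keep], list(cm.sample_ids), cm.batch
    )


def read_labels(path: str | Path, sample_ids: Sequence[str] | None = None) -> LabelVector:
    """Read a two-column (sample_id, class) table and code the two classes 0/1.

    Class codes follow sorted class-name order.  When ``sample_ids`` is given the
    labels are re-aligned to that sample order; every requested ID must appear.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#", dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"label file {path} must have exactly two columns")
    # tolerate an optional header line
    if df.iloc[0, 0].lower() in {"sample_id", "sample", "id"}:
        df = df.iloc[1:]
    ids = df.iloc[:, 0].tolist()
    classes = df.iloc[:, 1].tolist()
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate sample IDs in label file {path}")
    names = sorted(set(classes))
    if len(names) != 2:
        raise ValidationError(
            f"label file {path} must define exactly two classes, found {len(names)}"
        )
    by_id = dict(zip(ids, classes))
    if sample_ids is not None:
        missing = [s for s in sample_ids if str(s) not in by_id]
        if missing:
            raise ValidationError(f"label file {path} is missing sample IDs: {missing[:5]}")
        classes = [by_id[str(s)] for s in sample_ids]
    codes = np.array([names.index(c) for c in classes], dtype=np.int64)
    return LabelVector(codes, (names[0], names[1]))


def read_batch(path: str | Path, sample_ids: Sequence[str]) -> list[str]:
    """Read a two-column (sample_id, batch) table aligned to ``sample_ids``."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#", dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"batch file {path} must have exactly two columns")
    if df.iloc[0, 0].lower() in {"sample_id", "sample", "id"}:
        df = df.iloc[1:]
    by_id = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    missing = [s for s in sample_ids if str(s) not in by_id]
    if missing:
        raise ValidationError(f"batch file {path} is missing sample IDs: {missing[:5]}")
    return [by_id[str(s)] for s in sample_ids]


def write_score_table(scores, path: str | Path) -> None:
    """Write a ScoreTable as TSV with one named column per criterion."""
    df = pd.DataFrame(scores.scores, index=scores.gene_ids, columns=list(scores.criteria))
    df.to_csv(path, sep="\t", index_label="gene_id")


def write_gene_list(gene_ids: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gene_ids))


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def _sep_for(dialect: str) -> str:
    try:
        return _DIALECT_SEP[dialect]
    except KeyError:
        raise FormatError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'") from None
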