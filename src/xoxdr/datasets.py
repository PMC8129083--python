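"""Labeled feature matrices and their file I/O.

The universal input is a :class:`LabeledDataset`: an ``n x p`` real matrix
(rows are samples, columns are features) together with one class label per
row.  Labels may be arbitrary hashables (strings, ints); internally they are
coded ``0..C-1`` in order of first appearance, and the original names are
retained in :attr:`LabeledDataset.classes`.

Dense matrices are read from delimited text (CSV/TSV) via pandas; sparse
input uses MatrixMarket coordinate format (densified on load).  Matrices
with missing or non-finite entries are rejected -- the methods in this
package assume complete data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .exceptions import DimensionError, LoadError

__all__ = ["LabeledDataset", "load_labeled_matrix", "save_labeled_matrix"]


@dataclass
class LabeledDataset:
    """An ``n x p`` feature matrix with per-sample class labels.

    Parameters
    ----------
    X
        Real matrix of shape ``(n, p)``; coerced to float64.
    y
        Integer class codes of shape ``(n,)`` taking values ``0..C-1``.
    classes
        The original label of each class code, length ``C``.
    """

    X: np.ndarray
    y: np.ndarray
    classes: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise DimensionError(f"X must be 2-D, got shape {self.X.shape}")
        self.y = np.asarray(self.y)
        if self.y.ndim != 1 or self.y.shape[0] != self.X.shape[0]:
            raise DimensionError(
                f"label vector has {self.y.shape} entries for {self.X.shape[0]} rows"
            )
        if self.classes is None:
            self.classes = np.unique(self.y)
        self.classes = np.asarray(self.classes)
        if not np.issubdtype(self.y.dtype, np.integer):
            # labels given by name: recode in order of first appearance
            self.y, self.classes = _factorize(self.y)
        self.y = self.y.astype(np.intp)
        n, p = self.X.shape
        if n < 2 or p < 1:
            raise DimensionError(f"need n >= 2 and p >= 1, got n={n}, p={p}")
        if len(self.classes) < 2:
            raise DimensionError("need at least 2 classes")
        if self.y.min() < 0 or self.y.max() >= len(self.classes):
            raise DimensionError("label codes out of range for the class list")
        counts = np.bincount(self.y, minlength=len(self.classes))
        if (counts == 0).any():
            empty = self.classes[counts == 0]
            raise DimensionError(f"class(es) {list(empty)} have no samples")
        if not np.isfinite(self.X).all():
            i, j = np.argwhere(~np.isfinite(self.X))[0]
            raise LoadError(
                f"non-finite entry at row {i + 1}, column {j + 1} (1-based)"
            )

    # -- convenience views ------------------------------------------------

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.n_classes)

    @property
    def priors(self) -> np.ndarray:
        """Per-class sample proportions."""
        return self.counts / self.n

    @property
    def class_index(self) -> dict:
        """Mapping original class label -> array of sample indices."""
        return {
            lab: np.flatnonzero(self.y == c) for c, lab in enumerate(self.classes)
        }

    @classmethod
    def from_arrays(cls, X, labels) -> "LabeledDataset":
        """Build a dataset from a matrix and raw (possibly string) labels."""
        codes, classes = _factorize(np.asarray(labels))
        return cls(np.asarray(X, dtype=np.float64), codes, classes)


def _factorize(labels: np.ndarray):
    """Code labels 0..C-1 in order of first appearance."""
    classes = list(dict.fromkeys(labels.tolist()))
    lookup = {lab: c for c, lab in enumerate(classes)}
    codes = np.array([lookup[lab] for lab in labels.tolist()], dtype=np.intp)
    return codes, np.asarray(classes)


def _infer_sep(path: str, dialect: str | None) -> str:
    if dialect is not None:
        return {"csv": ",", "tsv": "\t"}.get(dialect, dialect)
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _read_matrix(path: str, dialect: str | None) -> np.ndarray:
    if not os.path.exists(path):
        raise LoadError(f"no such file: {path}")
    if str(path).endswith(".mtx"):
        M = scipy.io.mmread(path)
        if scipy.sparse.issparse(M):
            M = M.toarray()
        return np.asarray(M, dtype=np.float64)
    try:
        frame = pd.read_csv(
            path, sep=_infer_sep(path, dialect), header=None,
            float_precision="round_trip",
        )
    except Exception as exc:  # malformed text
        raise LoadError(f"could not parse {path}: {exc}") from exc
    if frame.iloc[0].map(lambda v: isinstance(v, str)).any():
        # a header row of column names: re-read keeping it out of the data
        frame = pd.read_csv(
            path, sep=_infer_sep(path, dialect), header=0,
            float_precision="round_trip",
        )
    try:
        return frame.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise LoadError(f"non-numeric entries in {path}: {exc}") from exc


def _read_labels(path: str, dialect: str | None) -> np.ndarray:
    col = pd.read_csv(path, sep=_infer_sep(path, dialect), header=None).iloc[:, 0]
    return col.to_numpy()


def load_labeled_matrix(
    matrix_path: str,
    labels_path_or_column,
    dialect: str | None = None,
) -> LabeledDataset:
    """Load a labeled dataset from delimited text or MatrixMarket files.

    ``labels_path_or_column`` is either a path to a one-column label file
    (one label per row of the matrix, same order) or, for headered CSV/TSV
    matrices, the name of the label column inside the matrix file.

    Raises :class:`LoadError` for missing files or non-finite entries and
    :class:`DimensionError` when the label count does not match the row
    count.
    """
    if os.path.exists(str(labels_path_or_column)):
        X = _read_matrix(matrix_path, dialect)
        labels = _read_labels(str(labels_path_or_column), dialect)
    else:
        if not os.path.exists(matrix_path):
            raise LoadError(f"no such file: {matrix_path}")
        frame = pd.read_csv(matrix_path, sep=_infer_sep(matrix_path, dialect), header=0)
        if labels_path_or_column not in frame.columns:
            raise LoadError(
                f"label column {labels_path_or_column!r} not found in {matrix_path} "
                "and no such label file exists"
            )
        labels = frame.pop(labels_path_or_column).to_numpy()
        try:
            X = frame.to_numpy(dtype=np.float64)
        except (TypeError, ValueError) as exc:
            raise LoadError(f"non-numeric entries in {matrix_path}: {exc}") from exc
    if len(labels) != X.shape[0]:
        raise DimensionError(
            f"{len(labels)} labels for {X.shape[0]} matrix rows"
        )
    return LabeledDataset.from_arrays(X, labels)


def save_labeled_matrix(data: LabeledDataset, matrix_path: str, labels_path: str) -> None:
    """Write a dataset back to a CSV matrix plus a one-column label file."""
    pd.DataFrame(data.X).to_csv(
        matrix_path, header=False, index=False, float_format="%.17g"
    )
    pd.Series(data.classes[data.y]).to_csv(labels_path, header=False, index=False)
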