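"""Plug-in Gaussian discriminant classifiers for embedded data.

LDA pools the class-centered covariance; QDA keeps one covariance per
class.  A small ridge ``eps = 1e-8 * trace(S)/d`` is always added to each
covariance because embedded dimensions can be collinear when ``d``
approaches ``n``.  Priors are the training class proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.stats import norm

from .exceptions import DimensionError

__all__ = [
    "GaussianClassifier",
    "fit_gaussian_classifier",
    "predict_classes",
    "closed_form_error",
]

_RIDGE_SCALE = 1e-8


@dataclass
class GaussianClassifier:
    """Fitted Gaussian discriminant rule in ``d`` dimensions."""

    kind: str                 # "lda" | "qda"
    priors: np.ndarray        # (C,)
    means: np.ndarray         # (C, d)
    covariances: np.ndarray   # (1, d, d) shared for LDA, (C, d, d) for QDA
    ridge: float

    @property
    def d(self) -> int:
        return self.means.shape[1]

    @property
    def n_classes(self) -> int:
        return self.means.shape[0]

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return predict_classes(self, Z)


def fit_gaussian_classifier(Z: np.ndarray, y: np.ndarray, kind: str = "lda") -> GaussianClassifier:
    """Plug-in LDA/QDA estimates on embedded data ``Z`` (n x d)."""
    if kind not in ("lda", "qda"):
        raise ValueError(f"unknown classifier kind {kind!r}")
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    if Z.ndim != 2:
        raise DimensionError("Z must be 2-D (samples x embedded dimensions)")
    y = np.asarray(y)
    if len(y) != Z.shape[0]:
        raise DimensionError(f"{len(y)} labels for {Z.shape[0]} samples")
    labels = np.unique(y)
    C = len(labels)
    n, d = Z.shape
    if d > n - C:
        warnings.warn(
            f"d={d} exceeds n-C={n - C}: covariance estimates are singular; "
            "relying on the ridge",
            stacklevel=2,
        )
    means = np.vstack([Z[y == lab].mean(axis=0) for lab in labels])
    priors = np.array([(y == lab).mean() for lab in labels])
    centered = Z - means[np.searchsorted(labels, y)]
    if kind == "lda":
        S = centered.T @ centered / n
        covs = S[None, :, :]
    else:
        covs = np.stack(
            [
                (centered[y == lab].T @ centered[y == lab]) / max((y == lab).sum(), 1)
                for lab in labels
            ]
        )
    ridge = float(_RIDGE_SCALE * np.trace(covs.sum(axis=0)) / (d * covs.shape[0]))
    covs = covs + ridge * np.eye(d)
    for S in covs:
        try:
            scipy.linalg.cholesky(S, lower=True)
        except scipy.linalg.LinAlgError as exc:
            raise DimensionError(
                "covariance is singular even after ridge regularization"
            ) from exc
    return GaussianClassifier(kind, priors, means, covs, ridge)


def predict_classes(clf: GaussianClassifier, Z: np.ndarray) -> np.ndarray:
    """Argmax of ``log prior + Gaussian log-density``; ties go to the lower
    class index."""
    Z = np.asarray(Z, dtype=np.float64)
    one_dim = Z.ndim == 1
    if one_dim:
        Z = Z[None, :]
    if Z.shape[1] != clf.d:
        raise DimensionError(f"Z has {Z.shape[1]} columns, classifier expects {clf.d}")
    scores = np.empty((Z.shape[0], clf.n_classes))
    for c in range(clf.n_classes):
        S = clf.covariances[0 if clf.kind == "lda" else c]
        L = scipy.linalg.cholesky(S, lower=True)
        diff = Z - clf.means[c]
        sol = scipy.linalg.solve_triangular(L, diff.T, lower=True)
        maha = (sol**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        scores[:, c] = np.log(clf.priors[c]) - 0.5 * (maha + logdet)
    labels = np.argmax(scores, axis=1)  # first max -> lowest class index on ties
    return labels[0] if one_dim else labels


def closed_form_error(s: float, priors=(0.5, 0.5)) -> float:
    """Bayes error of the two-class equal-covariance Gaussian problem.

    ``s`` is the Fisher signal-to-noise ratio ``delta' Sigma^-1 delta``.
    With equal priors the error is ``Phi(-sqrt(s)/2)``; with unequal priors
    the log-prior-ratio shifts the likelihood-ratio threshold.
    """
    if s < 0:
        raise ValueError(f"Fisher SNR must be nonnegative, got {s}")
    pi0, pi1 = priors
    if not np.isclose(pi0 + pi1, 1.0) or min(pi0, pi1) <= 0:
        raise ValueError("priors must be positive and sum to 1")
    if s == 0:
        return float(min(pi0, pi1))
    root = np.sqrt(s)
    c = np.log(pi0 / pi1)
    return float(
        pi0 * norm.cdf(-(c + s / 2.0) / root) + pi1 * norm.cdf((c - s / 2.0) / root)
    )
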