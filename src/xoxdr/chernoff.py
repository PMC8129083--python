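"""Chernoff information between multivariate Gaussians.

The Chernoff information between two distributions is the exponential decay
rate of the Bayes error of the optimal test, and therefore a natural score
for how well a (projected) two-class Gaussian problem can be classified.
An embedding ``W`` is evaluated by pushing the population through it
(:func:`project_gaussians`) and maximizing the Chernoff divergence

``C(t) = t(1-t)/2 * delta' Sigma_t^{-1} delta
        + 1/2 * ln( det Sigma_t / (det Sigma_0^{1-t} det Sigma_1^{t}) )``

with ``delta = mu_1 - mu_0`` and ``Sigma_t = (1-t) Sigma_0 + t Sigma_1``,
over ``t in (0, 1)``.  Values are in nats.  For equal covariances the
maximum is at ``t = 1/2`` with value ``delta' Sigma^{-1} delta / 8``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.optimize import minimize_scalar

from .exceptions import DimensionError

__all__ = [
    "GaussianPair",
    "ChernoffResult",
    "project_gaussians",
    "chernoff_divergence",
    "chernoff_information",
]


@dataclass
class GaussianPair:
    """Two Gaussian class-conditional distributions with priors."""

    mu0: np.ndarray
    mu1: np.ndarray
    cov0: np.ndarray
    cov1: np.ndarray
    priors: tuple = (0.5, 0.5)

    def __post_init__(self):
        self.mu0 = np.atleast_1d(np.asarray(self.mu0, dtype=np.float64))
        self.mu1 = np.atleast_1d(np.asarray(self.mu1, dtype=np.float64))
        self.cov0 = np.atleast_2d(np.asarray(self.cov0, dtype=np.float64))
        self.cov1 = np.atleast_2d(np.asarray(self.cov1, dtype=np.float64))
        p = self.mu0.shape[0]
        for name, arr in (("mu1", self.mu1),):
            if arr.shape != (p,):
                raise DimensionError(f"{name} has shape {arr.shape}, expected ({p},)")
        for name, S in (("cov0", self.cov0), ("cov1", self.cov1)):
            if S.shape != (p, p):
                raise DimensionError(f"{name} has shape {S.shape}, expected ({p}, {p})")
            if not np.allclose(S, S.T, atol=1e-10 * max(1.0, np.abs(S).max())):
                raise ValueError(f"{name} is not symmetric")
        for name, S in (("cov0", self.cov0), ("cov1", self.cov1)):
            try:
                scipy.linalg.cholesky(0.5 * (S + S.T), lower=True)
            except scipy.linalg.LinAlgError as exc:
                raise ValueError(f"{name} is not positive definite") from exc

    @property
    def dim(self) -> int:
        return self.mu0.shape[0]

    @property
    def delta(self) -> np.ndarray:
        return self.mu1 - self.mu0


@dataclass
class ChernoffResult:
    """Optimizing exponent ``t*`` and the Chernoff information (nats)."""

    t_star: float
    value: float


def project_gaussians(pair: GaussianPair, W: np.ndarray) -> GaussianPair:
    """Push a Gaussian pair through a full-column-rank projection ``W``.

    Means become ``W' mu_c`` and covariances ``W' Sigma_c W``.
    """
    W = np.asarray(W, dtype=np.float64)
    if W.ndim == 1:
        W = W[:, None]
    if W.shape[0] != pair.dim:
        raise DimensionError(
            f"W has {W.shape[0]} rows but the pair lives in {pair.dim} dimensions"
        )
    sv = scipy.linalg.svdvals(W)
    if W.shape[1] > W.shape[0] or sv[-1] <= 1e-12 * sv[0]:
        raise DimensionError("W must have full column rank")
    return GaussianPair(
        W.T @ pair.mu0,
        W.T @ pair.mu1,
        W.T @ pair.cov0 @ W,
        W.T @ pair.cov1 @ W,
        pair.priors,
    )


def chernoff_divergence(pair: GaussianPair, t: float) -> float:
    """Gaussian Chernoff divergence at exponent ``t`` (nats)."""
    if not (0.0 < t < 1.0):
        raise ValueError(f"t must lie strictly in (0, 1), got {t}")
    St = (1.0 - t) * pair.cov0 + t * pair.cov1
    delta = pair.delta
    try:
        L = scipy.linalg.cholesky(St, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("interpolated covariance is not positive definite") from exc
    sol = scipy.linalg.solve_triangular(L, delta, lower=True)
    quad = float(sol @ sol)
    logdet_t = 2.0 * np.log(np.diag(L)).sum()
    logdet_0 = _logdet(pair.cov0)
    logdet_1 = _logdet(pair.cov1)
    return float(
        0.5 * t * (1.0 - t) * quad
        + 0.5 * (logdet_t - (1.0 - t) * logdet_0 - t * logdet_1)
    )


def _logdet(S: np.ndarray) -> float:
    L = scipy.linalg.cholesky(S, lower=True)
    return 2.0 * float(np.log(np.diag(L)).sum())


def chernoff_information(pair: GaussianPair) -> ChernoffResult:
    """Maximize the Chernoff divergence over ``t in (0, 1)``.

    A coarse grid locates the basin (``C(t)`` is smooth and in practice
    unimodal for Gaussians; the grid guards against rare multimodality),
    then bounded scalar minimization refines ``t*`` to ``1e-10``.
    """
    grid = np.linspace(0.01, 0.99, 99)
    vals = np.array([chernoff_divergence(pair, t) for t in grid])
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda t: -chernoff_divergence(pair, float(np.clip(t, 1e-12, 1 - 1e-12))),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    t_star = float(res.x)
    value = max(float(-res.fun), float(vals[k]))
    return ChernoffResult(t_star=t_star, value=max(value, 0.0))
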