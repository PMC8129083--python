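"""Gaussian simulation populations with exact parameters.

Each setting is a fully specified population (:class:`GaussianSetting`), so
Bayes error and Chernoff information are computable from the true
parameters, not just estimable from samples.  Covariances are stored in
structured form -- per-class diagonal variances plus an optional shared
orthogonal rotation -- so sampling and density evaluation stay ``O(n p)``
(plus one rotation) even at large ``p``.

Settings
--------
``trunk2``
    Two classes, shared diagonal covariance with variances *increasing*
    along the coordinate index (``sigma_j^2 = maxvar / sqrt(p + 1 - j)``)
    while the mean-difference magnitudes *decrease*
    (``delta_j = 2 b / sqrt(2 j - 1)``).  The discriminating directions are
    therefore the low-variance coordinates: adversarial for variance-seeking
    projections, ideal for mean-difference ones.
``trunk3``
    Three equiprobable classes on the trunk2 covariance, at ``-delta``,
    ``0`` and ``delta + rev(delta)`` (the difference pattern with the
    coordinate order reversed), so both between-class directions carry
    signal.
``rotated_trunk``
    trunk2 conjugated by a seeded Haar-random rotation: no single original
    coordinate is informative, only linear combinations.
``cigars``
    Mean difference aligned with the dominant variance direction and
    concentrated in one coordinate; easy for every method.
``cross``
    Equal means, per-class covariances spiked along *orthogonal* axes;
    only class-specific second moments (QOQ + QDA) separate the classes
    efficiently.
``robust``
    trunk2 with a fraction ``rho`` of *training* samples drawn with noise
    inflated ``x scale`` (labels kept, test data clean): rewards robust
    location estimates.
``spherical``
    Isotropic shared covariance with the mean difference along a seeded
    random direction, calibrated to a 2% Bayes error; the class-centered
    covariance carries no class information at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .classifiers import closed_form_error
from .chernoff import GaussianPair
from .datasets import LabeledDataset
from .exceptions import DimensionError

__all__ = [
    "GaussianSetting",
    "SETTING_NAMES",
    "make_setting",
    "sample_from",
    "rotate_setting",
    "haar_rotation",
    "bayes_predict",
]

SETTING_NAMES = (
    "trunk2",
    "trunk3",
    "rotated_trunk",
    "cigars",
    "cross",
    "robust",
    "spherical",
)

_BAYES_MC_N = 100_000
_BAYES_MC_SEED = 123456789


@dataclass
class GaussianSetting:
    """Population parameters of a simulation setting.

    ``means`` are the final (possibly rotated) class means; covariances are
    ``Q diag(variances[c]) Q'`` with a shared orthogonal ``Q`` (identity
    when ``rotation`` is None).  ``contamination`` is ``(rho, scale)`` for
    the outlier setting, applied to training draws only.
    """

    name: str
    priors: np.ndarray            # (C,)
    means: np.ndarray             # (C, p)
    variances: np.ndarray         # (C, p) diagonal of the unrotated covariance
    rotation: np.ndarray | None = None
    contamination: tuple | None = None   # (rho, scale)
    meta: dict = field(default_factory=dict)
    _bayes_cache: float | None = field(default=None, repr=False)

    def __post_init__(self):
        self.priors = np.asarray(self.priors, dtype=np.float64)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=np.float64))
        if self.rotation is not None:
            Q = np.asarray(self.rotation, dtype=np.float64)
            if not np.allclose(Q.T @ Q, np.eye(Q.shape[1]), atol=1e-10):
                raise ValueError("rotation must be orthogonal (Q'Q = I to 1e-10)")
            self.rotation = Q
        if (self.variances <= 0).any():
            raise ValueError("variances must be positive")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")

    # -- basic descriptors -------------------------------------------------

    @property
    def p(self) -> int:
        return self.means.shape[1]

    @property
    def n_classes(self) -> int:
        return self.means.shape[0]

    @property
    def shared_covariance(self) -> bool:
        return bool(np.ptp(self.variances, axis=0).max() == 0.0)

    def cov(self, c: int) -> np.ndarray:
        """Materialize the p x p covariance of class ``c``."""
        D = np.diag(self.variances[c])
        if self.rotation is None:
            return D
        return self.rotation @ D @ self.rotation.T

    def gaussian_pair(self) -> GaussianPair:
        """The population as a :class:`GaussianPair` (two-class settings)."""
        if self.n_classes != 2:
            raise DimensionError("gaussian_pair is defined for two-class settings")
        return GaussianPair(
            self.means[0], self.means[1], self.cov(0), self.cov(1),
            tuple(self.priors),
        )

    @property
    def fisher_snr(self) -> float | None:
        """``delta' Sigma^{-1} delta`` for two-class shared-covariance
        settings (rotation-invariant); None otherwise."""
        if self.n_classes != 2 or not self.shared_covariance:
            return None
        delta = self.means[1] - self.means[0]
        if self.rotation is not None:
            delta = self.rotation.T @ delta
        return float(np.sum(delta**2 / self.variances[0]))

    @property
    def bayes_error(self) -> float:
        """Bayes error of the population: closed form for two-class shared
        covariance, cached Monte-Carlo (1e5 clean draws) otherwise."""
        s = self.fisher_snr
        if s is not None:
            return closed_form_error(s, tuple(self.priors))
        if self._bayes_cache is None:
            self._bayes_cache = self.bayes_error_mc(_BAYES_MC_N, _BAYES_MC_SEED)
        return self._bayes_cache

    def bayes_error_mc(self, n: int, seed: int) -> float:
        """Monte-Carlo Bayes error using the true-parameter Bayes rule."""
        errors = 0
        rng_seed = seed
        done = 0
        chunk = max(1, min(n, 20_000_000 // max(self.p, 1)))
        while done < n:
            m = min(chunk, n - done)
            data = sample_from(self, m, seed=rng_seed, split="test")
            pred = bayes_predict(self, data.X)
            errors += int((pred != data.y).sum())
            done += m
            rng_seed += 1
        return errors / n


def bayes_predict(setting: GaussianSetting, X: np.ndarray) -> np.ndarray:
    """Classify rows of ``X`` with the true-parameter Bayes rule."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != setting.p:
        raise DimensionError(f"X has {X.shape[1]} columns, setting has p={setting.p}")
    Z = X if setting.rotation is None else X @ setting.rotation
    mus = (
        setting.means
        if setting.rotation is None
        else setting.means @ setting.rotation
    )
    scores = np.empty((X.shape[0], setting.n_classes))
    for c in range(setting.n_classes):
        v = setting.variances[c]
        diff = Z - mus[c]
        scores[:, c] = (
            np.log(setting.priors[c])
            - 0.5 * np.sum(diff**2 / v, axis=1)
            - 0.5 * np.log(v).sum()
        )
    return np.argmax(scores, axis=1)


# ---------------------------------------------------------------------------
# setting constructors


def _trunk_variances(p: int, maxvar: float) -> np.ndarray:
    # increasing with the coordinate index, top value maxvar
    return maxvar / np.sqrt(np.arange(p, 0, -1, dtype=np.float64))


def _trunk_delta(p: int, b: float) -> np.ndarray:
    # decreasing mean-difference magnitudes
    return 2.0 * b / np.sqrt(2.0 * np.arange(1, p + 1, dtype=np.float64) - 1.0)


def make_setting(name: str, p: int = 100, **params) -> GaussianSetting:
    """Construct a named simulation population of dimensionality ``p``.

    Keyword overrides: ``b`` and ``maxvar`` (trunk family), ``snr``
    (cigars), ``rho`` and ``scale`` (robust), ``bayes`` and ``seed``
    (spherical direction / rotation seed).
    """
    if name not in SETTING_NAMES:
        raise ValueError(f"unknown setting {name!r}; choose from {SETTING_NAMES}")
    if p < 2 or (name == "trunk3" and p < 3):
        raise DimensionError(f"p={p} too small for setting {name!r}")

    if name in ("trunk2", "robust", "rotated_trunk"):
        b = params.get("b", 4.0)
        maxvar = params.get("maxvar", 100.0)
        v = _trunk_variances(p, maxvar)
        delta = _trunk_delta(p, b)
        means = np.vstack([-delta / 2.0, delta / 2.0])
        setting = GaussianSetting(
            "trunk2", np.array([0.5, 0.5]), means, np.vstack([v, v])
        )
        if name == "robust":
            setting.name = "robust"
            setting.contamination = (params.get("rho", 0.2), params.get("scale", 10.0))
        elif name == "rotated_trunk":
            setting = rotate_setting(setting, seed=params.get("seed", 0))
            setting.name = "rotated_trunk"
        return setting

    if name == "trunk3":
        b = params.get("b", 4.0)
        maxvar = params.get("maxvar", 100.0)
        v = _trunk_variances(p, maxvar)
        delta = _trunk_delta(p, b)
        means = np.vstack([-delta, np.zeros(p), delta + delta[::-1]])
        return GaussianSetting(
            "trunk3", np.full(3, 1.0 / 3.0), means, np.vstack([v, v, v])
        )

    if name == "cigars":
        snr = params.get("snr", 9.0)
        v = np.ones(p)
        v[0] = 100.0
        j = np.arange(2, p + 1, dtype=np.float64)
        shape = np.concatenate([[1.0], 0.1 / np.sqrt(j)])
        K = np.sqrt(snr / np.sum(shape**2 / v))
        delta = K * shape
        means = np.vstack([-delta / 2.0, delta / 2.0])
        return GaussianSetting("cigars", np.array([0.5, 0.5]), means, np.vstack([v, v]))

    if name == "cross":
        spike = params.get("spike", 100.0)
        v0 = np.ones(p)
        v0[0] = spike
        v1 = np.ones(p)
        v1[1] = spike
        means = np.zeros((2, p))
        return GaussianSetting("cross", np.array([0.5, 0.5]), means, np.vstack([v0, v1]))

    # spherical
    bayes = params.get("bayes", 0.02)
    seed = params.get("seed", 0)
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(p)
    u /= np.linalg.norm(u)
    norm_delta = 2.0 * norm.ppf(1.0 - bayes)
    delta = norm_delta * u
    means = np.vstack([-delta / 2.0, delta / 2.0])
    return GaussianSetting(
        "spherical", np.array([0.5, 0.5]), means, np.ones((2, p)),
        meta={"direction_seed": seed},
    )


# ---------------------------------------------------------------------------
# sampling and rotation


def sample_from(
    setting: GaussianSetting, n: int, seed: int, split: str = "train"
) -> LabeledDataset:
    """Draw ``n`` seeded samples from the population.

    Labels are multinomial draws from the priors (balanced in expectation).
    For contaminated settings the outlier mechanism applies to the *train*
    split only; the test split is always clean.
    """
    if split not in ("train", "test"):
        raise ValueError(f"unknown split {split!r}")
    if n < setting.n_classes:
        raise DimensionError(
            f"need n >= C = {setting.n_classes} samples, got n={n}"
        )
    rng = np.random.default_rng(seed)
    y = rng.choice(setting.n_classes, size=n, p=setting.priors)
    Z = rng.standard_normal((n, setting.p))
    if setting.contamination is not None and split == "train":
        rho, scale = setting.contamination
        outliers = rng.random(n) < rho
        Z[outliers] *= scale
    X = Z * np.sqrt(setting.variances[y])
    if setting.rotation is not None:
        X = X @ setting.rotation.T
    X += setting.means[y]
    return LabeledDataset(X, y, classes=np.arange(setting.n_classes))


def haar_rotation(p: int, seed: int) -> np.ndarray:
    """Seeded Haar-distributed orthogonal matrix (QR with sign-fixed
    diagonal)."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((p, p))
    Q, R = np.linalg.qr(A)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q * signs


def rotate_setting(
    setting: GaussianSetting, seed: int | None = None, Q: np.ndarray | None = None
) -> GaussianSetting:
    """Apply a (seeded Haar or given) rotation to means and covariances.

    The Fisher SNR and Bayes error are invariant; rotations compose, and the
    applied ``Q`` is recorded in ``meta['last_rotation']``.
    """
    if Q is None:
        if seed is None:
            raise ValueError("provide either a seed or an explicit rotation Q")
        Q = haar_rotation(setting.p, seed)
    Q = np.asarray(Q, dtype=np.float64)
    new_rot = Q if setting.rotation is None else Q @ setting.rotation
    meta = dict(setting.meta)
    meta["last_rotation"] = Q
    return GaussianSetting(
        setting.name,
        setting.priors.copy(),
        setting.means @ Q.T,
        setting.variances.copy(),
        rotation=new_rot,
        contamination=setting.contamination,
        meta=meta,
    )
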