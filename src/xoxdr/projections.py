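"""Class-conditional moments and supervised low-rank projections.

This module builds the XOX family of projections for wide (``p >= n``) data
and the standard baselines it is compared against:

* **LOL** -- concatenate the ``C-1`` class mean(or median)-difference
  directions with the top eigenvectors of the *class-centered* covariance
  (the covariance computed after subtracting each sample's own class
  location).  With the coordinate-wise class median as the location
  estimate this is the robust variant (RLOL); the median is this package's
  default, the mean the documented alternative.
* **QOQ** -- same first block, but the eigenvector block is drawn from each
  class's own centered matrix, pooled and sorted by singular value; pair
  with QDA downstream.
* **LFL** -- same first block, eigenvectors replaced by seeded very sparse
  random-projection columns.
* Baselines: PCA (pooled-centered eigenvectors), rrLDA (class-centered
  eigenvectors only), random projections, label-indicator CCA and PLS.

All eigenvector computations factor the ``n x p`` centered matrix directly
(economy SVD), never a ``p x p`` covariance, so the cost is linear in ``p``
at fixed ``n`` and ``d``.  Fitting at dimension ``d`` is *nested*: the first
``d'`` columns of the model equal the model fit at ``d'`` bit-for-bit for
the exact solver, so a single fit serves every smaller dimension.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.utils.extmath import randomized_svd

from .datasets import LabeledDataset
from .exceptions import DegenerateDataError, DimensionError, ParseError

__all__ = [
    "ClassMoments",
    "XoxConfig",
    "ProjectionModel",
    "class_moments",
    "delta_basis",
    "fit_xox",
    "fit_lol",
    "fit_qoq",
    "fit_lfl",
    "fit_pca",
    "fit_rrlda",
    "fit_rp",
    "fit_cca",
    "fit_pls",
    "transform",
    "nested_truncate",
    "save_projection",
    "load_projection",
]

_MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# linear-algebra helpers


def _economy_svd(M: np.ndarray):
    """Economy SVD of a (possibly wide) matrix.

    Every exact eigenvector computation in this module is routed through
    here, so tests can instrument the shapes that are actually factorized
    (the scalability contract: never a p x p array).
    """
    return scipy.linalg.svd(M, full_matrices=False)


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Sign convention for eigenvector columns.

    The entry of largest absolute value in each column is made positive;
    ties resolve to the lowest row index (``argmax`` returns the first
    maximum).  Purely a reproducibility convention.
    """
    if V.size == 0:
        return V
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def _unit_columns(W: np.ndarray) -> np.ndarray:
    # per-column norms on contiguous copies: the reduction order (and hence
    # the last bit) must not depend on how many columns sit alongside
    norms = np.array(
        [np.linalg.norm(np.ascontiguousarray(W[:, j])) for j in range(W.shape[1])]
    )
    if (norms == 0).any():
        raise DegenerateDataError("zero-norm projection column")
    return W / norms


# ---------------------------------------------------------------------------
# class moments


@dataclass
class ClassMoments:
    """Per-class first moments and the class-centered second moment.

    ``class_centered`` holds each sample minus its own class location; the
    class-centered covariance is ``class_centered.T @ class_centered / n``
    (maximum-likelihood ``1/n`` denominator -- only eigenvector directions
    are consumed downstream, so the denominator cancels) and is only
    materialized on request via :meth:`cov_matrix`.
    """

    priors: np.ndarray            # (C,)
    locations: np.ndarray         # (C, p) mean or coordinate-wise median
    pooled_mean: np.ndarray       # (p,)
    class_centered: np.ndarray    # (n, p)
    y: np.ndarray                 # (n,) class codes
    location: str                 # estimator used: "mean" | "median"

    @property
    def n_classes(self) -> int:
        return len(self.priors)

    def per_class_centered(self, c: int) -> np.ndarray:
        return self.class_centered[self.y == c]

    def cov_matrix(self) -> np.ndarray:
        """Materialize the p x p class-centered covariance (small p only)."""
        M = self.class_centered
        return (M.T @ M) / M.shape[0]


def class_moments(data: LabeledDataset, location: str = "mean") -> ClassMoments:
    """Estimate class locations and the class-centered sample matrix.

    ``location`` selects the per-class location estimator: ``"mean"`` or the
    coordinate-wise ``"median"`` (the robust choice).
    """
    if location not in ("mean", "median"):
        raise ValueError(f"unknown location estimator {location!r}")
    est = np.mean if location == "mean" else np.median
    C = data.n_classes
    locs = np.empty((C, data.p))
    for c in range(C):
        locs[c] = est(data.X[data.y == c], axis=0)
    return ClassMoments(
        priors=data.priors,
        locations=locs,
        pooled_mean=data.X.mean(axis=0),
        class_centered=data.X - locs[data.y],
        y=data.y,
        location=location,
    )


def delta_basis(moments: ClassMoments) -> np.ndarray:
    """Orthonormal-ish basis of the between-class location differences.

    Two classes: the single unit column ``(mu_1 - mu_0) / ||mu_1 - mu_0||``.
    More classes: the top ``C - 1`` left singular vectors of the
    prior-weighted location-deviation matrix ``[sqrt(pi_c) (mu_c - mu_bar)]``
    (``mu_bar`` the prior-weighted average location), ordered by singular
    value.  The weighted-SVD form reduces to the two-class difference and is
    invariant to class relabelling.
    """
    locs, priors = moments.locations, moments.priors
    C = moments.n_classes
    scale = np.abs(locs).max()
    if C == 2:
        diff = locs[1] - locs[0]
        nrm = np.linalg.norm(diff)
        if nrm <= 1e-12 * max(scale, 1.0):
            raise DegenerateDataError(
                "class locations are identical: the mean-difference direction "
                "is undefined (fall back to eigenvector-only projections)"
            )
        return (diff / nrm)[:, None]
    mu_bar = priors @ locs
    D = (np.sqrt(priors)[:, None] * (locs - mu_bar)).T  # p x C
    U, s, _ = _economy_svd(D)
    if s[0] <= 1e-12 * max(scale, 1.0):
        raise DegenerateDataError(
            "all class locations are identical: no mean-difference directions"
        )
    k = C - 1
    if s[k - 1] <= 1e-12 * s[0]:
        warnings.warn(
            "degenerate between-class structure: some mean-difference "
            "directions have (numerically) zero singular value",
            stacklevel=2,
        )
    return _fix_signs(U[:, :k])


# ---------------------------------------------------------------------------
# projection model


@dataclass
class XoxConfig:
    """Switchboard for the XOX family.

    ``location`` picks the first-moment estimator, ``second_moment`` the
    column source after the mean-difference block (``shared_eig`` = LOL,
    ``per_class_eig`` = QOQ, ``sparse_rp`` = LFL), ``solver`` exact or
    randomized eigendecomposition, ``sparsity`` the nonzero probability of
    sparse random-projection columns (default ``1/sqrt(p)``).
    """

    location: str = "median"
    second_moment: str = "shared_eig"
    solver: str = "exact"
    sparsity: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.location not in ("mean", "median"):
            raise ValueError(f"unknown location {self.location!r}")
        if self.second_moment not in ("shared_eig", "per_class_eig", "sparse_rp"):
            raise ValueError(f"unknown second_moment {self.second_moment!r}")
        if self.solver not in ("exact", "randomized"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if self.sparsity is not None and not (0 < self.sparsity <= 1):
            raise ValueError("sparsity must lie in (0, 1]")


@dataclass
class ProjectionModel:
    """A fitted ``p x d`` linear projection with per-column provenance.

    ``column_kind[j]`` records where column ``j`` came from: ``mean_diff``,
    ``shared_eig``, ``class{c}_eig``, ``sparse_rp``, ``rp``, ``cca``,
    ``pls`` or ``pca``.  Non-random columns have unit Euclidean norm.
    Transforming is plain ``X @ W`` -- no recentering; location information
    lives in the downstream classifier.
    """

    W: np.ndarray
    column_kind: list
    method: str
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.ndim != 2:
            raise DimensionError("W must be 2-D")
        if len(self.column_kind) != self.W.shape[1]:
            raise DimensionError("one column_kind entry per column required")
        if not np.isfinite(self.W).all():
            raise DimensionError("projection contains non-finite entries")

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def d(self) -> int:
        return self.W.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return transform(self, X)

    def truncate(self, d: int) -> "ProjectionModel":
        return nested_truncate(self, d)


def transform(model: ProjectionModel, X: np.ndarray) -> np.ndarray:
    """Project samples: ``X @ W`` (rows are samples)."""
    X = np.asarray(X, dtype=np.float64)
    one_dim = X.ndim == 1
    if one_dim:
        X = X[None, :]
    if X.shape[1] != model.p:
        raise DimensionError(
            f"X has {X.shape[1]} columns but the model expects {model.p}"
        )
    Z = X @ model.W
    return Z[0] if one_dim else Z


def nested_truncate(model: ProjectionModel, d: int) -> ProjectionModel:
    """First ``d`` columns of a fitted model.

    For the exact solver this is bit-identical to refitting at ``d``: every
    fit computes the same full factorization and slices it.
    """
    if not (1 <= d <= model.d):
        raise DimensionError(f"cannot truncate a d={model.d} model to d={d}")
    meta = dict(model.fit_meta)
    meta["truncated_from"] = model.d
    return ProjectionModel(
        model.W[:, :d].copy(), list(model.column_kind[:d]), model.method, meta
    )


def _meta(data: LabeledDataset, **kw) -> dict:
    kw.setdefault("classes", [str(c) for c in data.classes])
    return kw


# ---------------------------------------------------------------------------
# XOX family


def _shared_eigvectors(moments: ClassMoments, r: int, solver: str, seed) -> np.ndarray:
    M = moments.class_centered
    n, p = M.shape
    if r > min(n, p):
        raise DimensionError(
            f"{r} class-centered eigenvectors requested but rank is at most {min(n, p)}"
        )
    if solver == "randomized":
        _, _, Vt = randomized_svd(
            M, n_components=r, n_oversamples=10, n_iter=2, random_state=seed
        )
        return _fix_signs(Vt.T)
    _, _, Vt = _economy_svd(M)
    return _fix_signs(Vt[:r].T)


def _per_class_eigvectors(moments: ClassMoments, r: int, solver: str, seed):
    """Pooled per-class eigenvectors, globally sorted by singular value.

    Per-class singular values are divided by sqrt(n_c) so unevenly sized
    classes compare on the covariance scale.  Ties keep the stable
    (class order, solver column) order.  No per-class quota.
    """
    entries = []  # (value, class, column)
    for c in range(moments.n_classes):
        Mc = moments.per_class_centered(c)
        kc = min(Mc.shape)
        if solver == "randomized":
            _, s, Vt = randomized_svd(
                Mc, n_components=kc, n_oversamples=10, n_iter=2, random_state=seed
            )
        else:
            _, s, Vt = _economy_svd(Mc)
        V = _fix_signs(Vt.T)
        for j in range(kc):
            entries.append((s[j] / np.sqrt(Mc.shape[0]), c, V[:, j]))
    if r > len(entries):
        raise DimensionError(
            f"{r} per-class eigenvectors requested but only {len(entries)} exist"
        )
    order = sorted(range(len(entries)), key=lambda i: -entries[i][0])
    cols, kinds = [], []
    for i in order[:r]:
        _, c, v = entries[i]
        cols.append(v)
        kinds.append(f"class{c}_eig")
    return np.column_stack(cols), kinds


def _rp_column(p: int, j: int, c: float, seed: int) -> np.ndarray:
    """Column ``j`` of a seeded sparse sign projection.

    Entries are +-1 with probability ``c/2`` each (0 otherwise), scaled by
    ``1/sqrt(p*c)`` for unit expected squared norm.  Each column has its own
    child seed, so the first ``d'`` columns never depend on ``d`` (nesting).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(j,)))
    nz = rng.random(p) < c
    signs = rng.integers(0, 2, size=p) * 2 - 1
    return (nz * signs) / np.sqrt(p * c)


def fit_xox(data: LabeledDataset, d: int, cfg: XoxConfig | None = None, **kw) -> ProjectionModel:
    """Fit an XOX-family projection at target dimension ``d``.

    Columns ``1..min(C-1, d)`` are the mean(/median)-difference directions;
    the remaining columns come from the configured second-moment source.
    Requesting ``d <= C-1`` yields a means-only projection (valid: those are
    the top embedding dimensions of the family).
    """
    cfg = cfg if cfg is not None else XoxConfig(**kw)
    if not (1 <= d <= data.p):
        raise DimensionError(f"need 1 <= d <= p={data.p}, got d={d}")
    moments = class_moments(data, cfg.location)
    B = delta_basis(moments)
    m = min(data.n_classes - 1, d)
    cols = [B[:, :m]]
    kinds = ["mean_diff"] * m
    r = d - m
    if r > 0:
        if cfg.second_moment == "shared_eig":
            cols.append(_shared_eigvectors(moments, r, cfg.solver, cfg.seed))
            kinds += ["shared_eig"] * r
        elif cfg.second_moment == "per_class_eig":
            V, vk = _per_class_eigvectors(moments, r, cfg.solver, cfg.seed)
            cols.append(V)
            kinds += vk
        else:  # sparse_rp
            c = cfg.sparsity if cfg.sparsity is not None else 1.0 / np.sqrt(data.p)
            seed = 0 if cfg.seed is None else cfg.seed
            cols.append(
                np.column_stack([_rp_column(data.p, j, c, seed) for j in range(r)])
            )
            kinds += ["sparse_rp"] * r
    name = {"shared_eig": "lol", "per_class_eig": "qoq", "sparse_rp": "lfl"}[
        cfg.second_moment
    ]
    meta = _meta(
        data,
        location=cfg.location,
        solver=cfg.solver,
        seed=cfg.seed,
        sparsity=cfg.sparsity,
    )
    return ProjectionModel(np.concatenate(cols, axis=1), kinds, name, meta)


def fit_lol(data, d, location="median", solver="exact", seed=None) -> ProjectionModel:
    """LOL: mean(/median)-difference directions + shared class-centered eigenvectors."""
    return fit_xox(data, d, XoxConfig(location=location, solver=solver, seed=seed))


def fit_qoq(data, d, location="median", solver="exact", seed=None) -> ProjectionModel:
    """QOQ: difference directions + per-class eigenvectors (use QDA downstream)."""
    return fit_xox(
        data, d, XoxConfig(location=location, second_moment="per_class_eig",
                           solver=solver, seed=seed)
    )


def fit_lfl(data, d, location="median", sparsity=None, seed=0) -> ProjectionModel:
    """LFL: difference directions + very sparse random-projection columns."""
    return fit_xox(
        data, d, XoxConfig(location=location, second_moment="sparse_rp",
                           sparsity=sparsity, seed=seed)
    )


# ---------------------------------------------------------------------------
# baselines


def fit_pca(data: LabeledDataset, d: int) -> ProjectionModel:
    """Top ``d`` eigenvectors of the pooled sample covariance (pooled-mean centered)."""
    if not (1 <= d <= min(data.n - 1, data.p)):
        raise DimensionError(
            f"PCA needs 1 <= d <= min(n-1, p) = {min(data.n - 1, data.p)}, got {d}"
        )
    M = data.X - data.X.mean(axis=0)
    _, _, Vt = _economy_svd(M)
    W = _fix_signs(Vt[:d].T)
    return ProjectionModel(W, ["pca"] * d, "pca", _meta(data))


def fit_rrlda(data: LabeledDataset, d: int, location: str = "mean") -> ProjectionModel:
    """Reduced-rank LDA: top ``d`` class-centered eigenvectors, no mean-difference column."""
    if not (1 <= d <= min(data.n, data.p)):
        raise DimensionError(
            f"rrLDA needs 1 <= d <= min(n, p) = {min(data.n, data.p)}, got {d}"
        )
    moments = class_moments(data, location)
    W = _shared_eigvectors(moments, d, "exact", None)
    return ProjectionModel(W, ["shared_eig"] * d, "rrlda", _meta(data, location=location))


def fit_rp(p: int, d: int, seed: int = 0, sparsity: float | None = None,
           scheme: str = "very_sparse") -> ProjectionModel:
    """Seeded sparse random projection with entries in {-1, 0, +1}.

    Nonzero probability ``sparsity`` defaults to ``1/sqrt(p)`` for the
    very-sparse scheme and ``1/3`` for the classic sparse scheme; columns are
    scaled to unit expected squared norm.
    """
    if not (1 <= d <= p):
        raise DimensionError(f"need 1 <= d <= p={p}, got d={d}")
    if sparsity is None:
        sparsity = 1.0 / np.sqrt(p) if scheme == "very_sparse" else 1.0 / 3.0
    if not (0 < sparsity <= 1):
        raise ValueError("sparsity must lie in (0, 1]")
    W = np.column_stack([_rp_column(p, j, sparsity, seed) for j in range(d)])
    return ProjectionModel(
        W, ["rp"] * d, "rp", {"seed": seed, "sparsity": sparsity, "scheme": scheme}
    )


def _indicator(y: np.ndarray, C: int) -> np.ndarray:
    Y = np.zeros((len(y), C))
    Y[np.arange(len(y)), y] = 1.0
    return Y


def fit_cca(data: LabeledDataset, d: int) -> ProjectionModel:
    """Label-indicator CCA directions via pseudo-inverse least squares.

    Canonical directions maximizing correlation between ``X`` and the class
    indicator matrix, computed regularization-free on the pooled-centered
    matrix's pseudo-inverse.  At most ``C - 1`` directions exist.  When
    ``p >= n`` this exhibits maximal data piling: every training sample of a
    class projects to the same point.
    """
    C = data.n_classes
    if not (1 <= d <= C - 1):
        raise DimensionError(
            f"label-indicator CCA has rank C-1 = {C - 1}; requested d={d}"
        )
    Xc = data.X - data.X.mean(axis=0)
    Yc = _indicator(data.y, C)
    Yc = Yc - Yc.mean(axis=0)
    Ux, sx, Vxt = _economy_svd(Xc)
    rx = int((sx > 1e-12 * sx[0]).sum())
    Uy, sy, _ = _economy_svd(Yc)
    ry = int((sy > 1e-12 * sy[0]).sum())
    K = Ux[:, :rx].T @ Uy[:, :ry]
    A, _, _ = _economy_svd(K)
    W = Vxt[:rx].T @ (A[:, :d] / sx[:rx, None])
    W = _fix_signs(_unit_columns(W))
    return ProjectionModel(W, ["cca"] * d, "cca", _meta(data))


def fit_pls(data: LabeledDataset, d: int) -> ProjectionModel:
    """Partial least squares directions against the class indicator matrix.

    Iterative deflation (NIPALS-style): each round takes the dominant left
    singular vector of the cross-covariance ``X_def' Y_def``, deflates both
    blocks by the extracted score, and finally converts the weights to
    rotations ``R = W (P'W)^{-1}`` so that ``X @ R`` reproduces the PLS
    scores without explicit deflation at transform time.
    """
    if not (1 <= d <= min(data.n - 1, data.p)):
        raise DimensionError(
            f"PLS needs 1 <= d <= min(n-1, p) = {min(data.n - 1, data.p)}, got {d}"
        )
    Xd = data.X - data.X.mean(axis=0)
    Yd = _indicator(data.y, data.n_classes)
    Yd = Yd - Yd.mean(axis=0)
    scale = np.linalg.norm(Xd) * max(np.linalg.norm(Yd), 1.0)
    Ws, Ps = [], []
    for _ in range(d):
        M = Xd.T @ Yd
        if np.linalg.norm(M) <= 1e-12 * max(scale, 1.0):
            raise DegenerateDataError(
                "zero cross-covariance between X and the labels: no further "
                "PLS directions exist"
            )
        u, _, _ = _economy_svd(M)
        w = u[:, 0]
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 1e-300:
            raise DegenerateDataError("degenerate PLS score (zero variance)")
        p_load = Xd.T @ t / tt
        q_load = Yd.T @ t / tt
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, q_load)
        Ws.append(w)
        Ps.append(p_load)
    # rotations by forward recurrence: r_j = w_j - sum_{i<j} (p_i'w_j) r_i,
    # the triangular solve of R (P'W) = W column by column -- manifestly
    # nested, so truncation is bit-identical to a smaller fit
    Rs = []
    for j, w in enumerate(Ws):
        r = w.copy()
        for i in range(j):
            r -= (Ps[i] @ w) * Rs[i]
        Rs.append(r / (Ps[j] @ r))
    R = _fix_signs(_unit_columns(np.column_stack(Rs)))
    return ProjectionModel(R, ["pls"] * d, "pls", _meta(data))


# ---------------------------------------------------------------------------
# serialization: a diff-able structured-text container


def save_projection(model: ProjectionModel, path: str) -> None:
    """Write a model as a text container: JSON metadata block + matrix block.

    Floats are printed with 17 significant digits, which round-trips IEEE
    double exactly.
    """
    header = {
        "format": "xoxdr-projection",
        "version": _MODEL_FORMAT_VERSION,
        "method": model.method,
        "shape": list(model.W.shape),
        "column_kind": list(model.column_kind),
        "fit_meta": _jsonable(model.fit_meta),
    }
    try:
        with open(path, "w") as fh:
            fh.write(json.dumps(header) + "\n")
            np.savetxt(fh, model.W, fmt="%.17g")
    except OSError as exc:
        raise IOError(f"cannot write projection to {path}: {exc}") from exc


def load_projection(path: str) -> ProjectionModel:
    """Read a model written by :func:`save_projection` (lossless round-trip)."""
    try:
        with open(path) as fh:
            first = fh.readline()
            try:
                header = json.loads(first)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: malformed metadata block: {exc}") from exc
            if not isinstance(header, dict) or header.get("format") != "xoxdr-projection":
                raise ParseError(f"{path}: not an xoxdr projection file")
            if header.get("version") != _MODEL_FORMAT_VERSION:
                raise ParseError(
                    f"{path}: unsupported format version {header.get('version')!r}"
                )
            for key in ("method", "shape", "column_kind", "fit_meta"):
                if key not in header:
                    raise ParseError(f"{path}: missing field {key!r}")
            try:
                W = np.loadtxt(fh, ndmin=2)
            except ValueError as exc:
                raise ParseError(f"{path}: malformed matrix block: {exc}") from exc
    except OSError as exc:
        raise IOError(f"cannot read projection from {path}: {exc}") from exc
    if list(W.shape) != list(header["shape"]):
        raise ParseError(
            f"{path}: matrix block has shape {list(W.shape)}, header says {header['shape']}"
        )
    return ProjectionModel(W, header["column_kind"], header["method"], header["fit_meta"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
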