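"""Cross-validated misclassification curves, Cohen's kappa and benchmarking.

The harness fits each embedding once per fold at the *largest* requested
dimension and reuses its nested truncations for every smaller dimension --
the family's hyper-parameter selection is nested, so sweeping ``d`` costs a
single fit.  Embeddings are always fit on the training folds only; the held
out fold is projected with the train-fold model before classification.

Per method, the selected dimension minimizes the mean cross-validated error
(ties to the smallest ``d``), and Cohen's kappa is computed at that
method's own selected dimension from the pooled out-of-fold confusion
table.  Method comparison follows the benchmark procedure: effect size
``kappa(reference) - kappa(method)`` (negative favors the method), within
dataset ranks of the selected-dimension mean errors, and paired two-sided
Wilcoxon signed-rank tests across datasets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, wilcoxon
from sklearn.model_selection import StratifiedKFold

from .classifiers import fit_gaussian_classifier, predict_classes
from .datasets import LabeledDataset
from .exceptions import DimensionError, XoxdrError
from . import projections as _proj

__all__ = [
    "EvalCurve",
    "METHODS",
    "crossval_curves",
    "cohens_kappa",
    "select_dim",
    "effect_size_and_ranks",
    "write_report",
    "read_report",
]


@dataclass
class EvalCurve:
    """Cross-validated error-vs-dimension curve for one method."""

    method: str
    dims: list
    fold_errors: np.ndarray       # (len(dims), k)
    kappa: float = None
    confusion: np.ndarray = None  # pooled out-of-fold confusion at selected_dim
    meta: dict = field(default_factory=dict)

    @property
    def mean_errors(self) -> np.ndarray:
        return np.asarray(self.fold_errors).mean(axis=1)

    @property
    def selected_dim(self) -> int:
        return select_dim(self)


def select_dim(curve: EvalCurve) -> int:
    """Dimension with the lowest mean cross-validated error (ties -> smallest d)."""
    if len(curve.dims) == 0:
        raise XoxdrError("empty curve")
    return int(curve.dims[int(np.argmin(curve.mean_errors))])


def cohens_kappa(confusion) -> float:
    """Chance-corrected agreement from a C x C confusion count table.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with observed agreement ``p_o`` and
    chance agreement ``p_e`` from the marginals; 0 means chance-level, 1
    perfect.  Degenerate marginals (``p_e = 1``) return 0 with a warning.
    """
    T = np.asarray(confusion, dtype=np.float64)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise DimensionError("confusion table must be square")
    if (T < 0).any() or T.sum() <= 0:
        raise ValueError("confusion table needs nonnegative counts, total > 0")
    N = T.sum()
    p_o = np.trace(T) / N
    p_e = float((T.sum(axis=1) / N) @ (T.sum(axis=0) / N))
    if p_e >= 1.0 - 1e-15:
        warnings.warn("degenerate marginals (p_e = 1); defining kappa = 0", stacklevel=2)
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


# ---------------------------------------------------------------------------
# method registry: name -> fit(train_dataset, d, seed) -> ProjectionModel

METHODS = {
    "lol": lambda ds, d, seed, **kw: _proj.fit_lol(
        ds, d, location=kw.get("location", "median"),
        solver=kw.get("solver", "exact"), seed=seed),
    "lol-mean": lambda ds, d, seed, **kw: _proj.fit_lol(
        ds, d, location="mean", solver=kw.get("solver", "exact"), seed=seed),
    "qoq": lambda ds, d, seed, **kw: _proj.fit_qoq(
        ds, d, location=kw.get("location", "median"), seed=seed),
    "lfl": lambda ds, d, seed, **kw: _proj.fit_lfl(
        ds, d, location=kw.get("location", "median"),
        sparsity=kw.get("sparsity"), seed=0 if seed is None else seed),
    "pca": lambda ds, d, seed, **kw: _proj.fit_pca(ds, d),
    "rrlda": lambda ds, d, seed, **kw: _proj.fit_rrlda(ds, d),
    "rp": lambda ds, d, seed, **kw: _proj.fit_rp(
        ds.p, d, seed=0 if seed is None else seed, sparsity=kw.get("sparsity")),
    "cca": lambda ds, d, seed, **kw: _proj.fit_cca(ds, d),
    "pls": lambda ds, d, seed, **kw: _proj.fit_pls(ds, d),
}


def _resolve(method):
    if callable(method):
        return getattr(method, "__name__", "custom"), method
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; known: {sorted(METHODS)}")
    return method, METHODS[method]


def crossval_curves(
    data: LabeledDataset,
    methods,
    dims,
    k: int = 5,
    classifier: str = "lda",
    seed: int = 0,
    **method_kw,
) -> list:
    """Stratified k-fold error-vs-dimension curves for several methods.

    ``methods`` is a list of registry names (``lol``, ``qoq``, ``lfl``,
    ``pca``, ``rrlda``, ``rp``, ``cca``, ``pls``, ``lol-mean``) and/or
    callables ``fit(dataset, d, seed) -> ProjectionModel``.  Each method is
    fit exactly once per fold, at ``max(dims)``, and truncated for the
    smaller dimensions.
    """
    dims = sorted(int(d) for d in dims)
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if dims[0] < 1 or dims[-1] > data.p:
        raise DimensionError(f"dims must lie in [1, p={data.p}]")
    if data.counts.min() < k:
        raise XoxdrError(
            f"smallest class has {data.counts.min()} samples < k={k} folds; "
            "use a smaller k"
        )
    dmax = dims[-1]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(data.X, data.y))
    resolved = [_resolve(m) for m in methods]
    curves = []
    for name, fitter in resolved:
        fold_errors = np.zeros((len(dims), k))
        # per-dim out-of-fold predictions for the pooled confusion table
        preds = {d: np.empty(data.n, dtype=np.intp) for d in dims}
        for f, (tr, te) in enumerate(folds):
            train = LabeledDataset(
                data.X[tr], data.y[tr], classes=np.arange(data.n_classes)
            )
            model = fitter(train, dmax, seed, **method_kw)
            Ztr = data.X[tr] @ model.W
            Zte = data.X[te] @ model.W
            for i, d in enumerate(dims):
                clf = fit_gaussian_classifier(Ztr[:, :d], data.y[tr], kind=classifier)
                yhat = predict_classes(clf, Zte[:, :d])
                fold_errors[i, f] = float((yhat != data.y[te]).mean())
                preds[d][te] = yhat
        curve = EvalCurve(
            name, dims, fold_errors,
            meta={"k": k, "classifier": classifier, "seed": seed},
        )
        sel = curve.selected_dim
        C = data.n_classes
        conf = np.zeros((C, C), dtype=np.int64)
        np.add.at(conf, (data.y, preds[sel]), 1)
        curve.confusion = conf
        curve.kappa = cohens_kappa(conf)
        curves.append(curve)
    return curves


def effect_size_and_ranks(curves_by_dataset: dict, reference: str = "pca"):
    """Benchmark comparison across datasets.

    Returns a dict with a per-dataset/method table (kappa, effect size
    ``kappa(reference) - kappa(method)`` at each method's selected
    dimension, selected-dimension mean error and its within-dataset rank,
    1 = best, ties averaged) and two-sided paired Wilcoxon signed-rank
    p-values between every method pair across datasets (exact null for
    <= 25 pairs, zero differences dropped).
    """
    if len(curves_by_dataset) < 1:
        raise XoxdrError("no datasets given")
    rows = []
    for ds_name, curves in curves_by_dataset.items():
        by_method = {c.method: c for c in curves}
        if reference not in by_method:
            raise XoxdrError(
                f"reference method {reference!r} missing for dataset {ds_name!r}"
            )
        kappa_ref = by_method[reference].kappa
        sel_errors = {
            m: float(c.mean_errors[c.dims.index(c.selected_dim)])
            for m, c in by_method.items()
        }
        ranks = rankdata(list(sel_errors.values()), method="average")
        rank_of = dict(zip(sel_errors.keys(), ranks))
        for m, c in by_method.items():
            rows.append(
                {
                    "dataset": ds_name,
                    "method": m,
                    "selected_dim": c.selected_dim,
                    "error": sel_errors[m],
                    "kappa": c.kappa,
                    "effect_size": kappa_ref - c.kappa,
                    "rank": rank_of[m],
                }
            )
    table = pd.DataFrame(rows)
    methods = sorted(table["method"].unique())
    pvals = {}
    n_ds = table["dataset"].nunique()
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            ea = table[table["method"] == a].set_index("dataset")["error"]
            eb = table[table["method"] == b].set_index("dataset")["error"]
            common = ea.index.intersection(eb.index)
            if len(common) < 2:
                raise XoxdrError(
                    "need at least 2 datasets for the signed-rank test"
                )
            diff = ea[common].to_numpy() - eb[common].to_numpy()
            if np.all(diff == 0):
                pvals[(a, b)] = 1.0
                continue
            method = "exact" if len(common) <= 25 else "auto"
            res = wilcoxon(
                diff, zero_method="wilcox", alternative="two-sided", method=method
            )
            pvals[(a, b)] = float(res.pvalue)
    return {"table": table, "wilcoxon_p": pvals, "n_datasets": n_ds}


# ---------------------------------------------------------------------------
# report I/O


def write_report(results: list, path: str, reference: str | None = None) -> None:
    """Write curves (and optional effect sizes vs a reference) as JSON."""
    if not results:
        raise XoxdrError("refusing to write an empty report")
    by_method = {c.method: c for c in results}
    payload = {"format": "xoxdr-report", "version": 1, "curves": []}
    for c in results:
        entry = {
            "method": c.method,
            "dims": list(c.dims),
            "fold_errors": np.asarray(c.fold_errors).tolist(),
            "mean_errors": c.mean_errors.tolist(),
            "kappa": c.kappa,
            "selected_dim": c.selected_dim,
            "confusion": None if c.confusion is None else np.asarray(c.confusion).tolist(),
            "meta": _proj._jsonable(c.meta),
        }
        if reference is not None and reference in by_method and c.method != reference:
            entry["effect_size"] = by_method[reference].kappa - c.kappa
        payload["curves"].append(entry)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_report(path: str) -> list:
    """Re-read a report written by :func:`write_report`."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "xoxdr-report":
        raise XoxdrError(f"{path}: not an xoxdr report")
    curves = []
    for e in payload["curves"]:
        curves.append(
            EvalCurve(
                e["method"], e["dims"], np.asarray(e["fold_errors"]),
                kappa=e["kappa"],
                confusion=None if e["confusion"] is None else np.asarray(e["confusion"]),
                meta=e.get("meta", {}),
            )
        )
    return curves
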