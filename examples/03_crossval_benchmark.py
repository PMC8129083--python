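"""Cross-validated benchmarking with nested dimension sweeps.

Runs the 5-fold stratified harness on a simulated wide dataset, sweeping
the embedding dimension for several methods at the cost of one fit per
fold (truncating a d-dimensional model yields every smaller model), then
prints each method's error curve, the selected dimension, Cohen's kappa,
and the effect size versus PCA (negative = better than PCA).
"""

from xoxdr import crossval_curves, effect_size_and_ranks, make_setting, sample_from

datasets = {
    "trunk_sim": sample_from(make_setting("trunk2", p=500), 150, seed=5),
    "cigars_sim": sample_from(make_setting("cigars", p=500), 150, seed=6),
    "spherical_sim": sample_from(make_setting("spherical", p=500), 150, seed=7),
}

curves_by_dataset = {}
for name, data in datasets.items():
    curves = crossval_curves(
        data, ["lol", "pca", "rrlda", "rp"], dims=[1, 2, 3, 5, 10], k=5, seed=0
    )
    curves_by_dataset[name] = curves
    print(name)
    for c in curves:
        errs = ", ".join(f"d={d}:{e:.3f}" for d, e in zip(c.dims, c.mean_errors))
        print(f"  {c.method:6s} {errs}  ->  selected d={c.selected_dim}, kappa={c.kappa:.3f}")

out = effect_size_and_ranks(curves_by_dataset, reference="pca")
print("\nmean effect size kappa(PCA) - kappa(method) across datasets "
      "(negative = beats PCA):")
t = out["table"]
for m, g in t[t.method != "pca"].groupby("method"):
    print(f"  {m:6s} {g.effect_size.mean():+.3f}   mean rank {g['rank'].mean():.1f}")
print("\npaired Wilcoxon signed-rank p-values (two-sided):")
for (a, b), p in out["wilcoxon_p"].items():
    print(f"  {a} vs {b}: p = {p:.3f}")
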