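"""Score embeddings by population Chernoff information.

The Chernoff information between the two projected class distributions is
the exponential rate at which the Bayes error of the projected problem
decays -- the tightest possible criterion for comparing embeddings.  We fit
LOL, rrLDA and PCA on a sample of the trunk population, push the *true*
population through each projection, and print the Chernoff curve per
dimension.  LOL dominates rrLDA everywhere (and PCA on this setting).
"""

from xoxdr import (
    chernoff_information,
    fit_lol,
    fit_pca,
    fit_rrlda,
    make_setting,
    nested_truncate,
    project_gaussians,
    sample_from,
)

setting = make_setting("trunk2", p=300)
pair = setting.gaussian_pair()
train = sample_from(setting, 100, seed=3, split="train")

models = {
    "lol": fit_lol(train, 6, location="mean"),
    "rrlda": fit_rrlda(train, 6),
    "pca": fit_pca(train, 6),
}

print("Chernoff information (nats) of the projected population:")
print("d    " + "".join(f"{m:>10s}" for m in models))
for d in range(1, 7):
    row = [
        chernoff_information(project_gaussians(pair, nested_truncate(m, d).W)).value
        for m in models.values()
    ]
    print(f"{d:<4d}" + "".join(f"{v:10.4f}" for v in row))
print("\nlarger = better separated classes after projection; the ambient-"
      f"\nspace ceiling is s/8 = {setting.fisher_snr / 8:.4f} nats")
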