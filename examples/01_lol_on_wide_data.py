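"""Fit LOL on a wide simulated problem and compare it with PCA and rrLDA.

Draws 100 training samples in 1000 dimensions from the two-class trunk
population (decaying mean differences, growing variances), projects to
three dimensions with each method, trains LDA on the embedding and reports
held-out misclassification.  LOL should sit near the Bayes error, PCA in
between, and rrLDA near chance (0.5): the class-centered eigenvectors
alone point at high-variance, uninformative coordinates.
"""

import numpy as np

from xoxdr import (
    fit_gaussian_classifier,
    fit_lol,
    fit_pca,
    fit_rrlda,
    make_setting,
    predict_classes,
    sample_from,
)

setting = make_setting("trunk2", p=1000)
print(f"population: p={setting.p}, Fisher SNR={setting.fisher_snr:.1f}, "
      f"Bayes error={setting.bayes_error:.2e}")

train = sample_from(setting, 100, seed=0, split="train")
test = sample_from(setting, 10_000, seed=1, split="test")

for name, fit in [
    ("LOL  (median)", lambda ds, d: fit_lol(ds, d)),
    ("PCA", fit_pca),
    ("rrLDA", fit_rrlda),
]:
    model = fit(train, 3)
    clf = fit_gaussian_classifier(train.X @ model.W, train.y, "lda")
    err = (predict_classes(clf, test.X @ model.W) != test.y).mean()
    print(f"{name:14s} d=3  held-out error = {err:.3f}")
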