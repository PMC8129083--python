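"""Robust and quadratic members of the XOX family.

Two situations where swapping one moment estimate changes everything:

* contaminated training data -- LOL with coordinate-wise class *medians*
  (the default) shrugs off 20% inflated-noise outliers that wreck the
  mean-location variant;
* equal class means with orthogonally spiked class covariances -- only
  QOQ, which keeps one eigenvector block per class and classifies with
  QDA, separates the classes.
"""

from xoxdr import (
    fit_gaussian_classifier,
    fit_lol,
    fit_qoq,
    make_setting,
    predict_classes,
    sample_from,
)


def err(setting, model_fn, clf_kind, seed=0, d=3):
    train = sample_from(setting, 100, seed=seed, split="train")
    test = sample_from(setting, 10_000, seed=seed + 1, split="test")
    model = model_fn(train, d)
    clf = fit_gaussian_classifier(train.X @ model.W, train.y, clf_kind)
    return (predict_classes(clf, test.X @ model.W) != test.y).mean()


robust = make_setting("robust", p=1000)   # trunk2 + 20% outliers in training
print("outlier-contaminated trunk (train only; test clean):")
print(f"  LOL, median location: {err(robust, lambda t, d: fit_lol(t, d), 'lda'):.3f}")
print(f"  LOL, mean   location: {err(robust, lambda t, d: fit_lol(t, d, location='mean'), 'lda'):.3f}")

cross = make_setting("cross", p=100)      # same means, orthogonal covariances
print(f"\ncross setting (Bayes error {cross.bayes_error:.3f}):")
print(f"  QOQ + QDA: {err(cross, lambda t, d: fit_qoq(t, d), 'qda'):.3f}")
print(f"  LOL + LDA: {err(cross, lambda t, d: fit_lol(t, d), 'lda'):.3f}"
      "   <- no linear rule can separate equal means")
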