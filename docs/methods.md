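# Methods

## The problem

Biomedical classification problems are routinely *wide*: the number of
features `p` (voxels, amplicons, probes) dwarfs the number of labeled
samples `n`.  Fisher's LDA needs the inverse of a `p x p` covariance that a
sample of size `n < p` cannot identify, and PCA -- the standard fallback --
ignores the labels entirely, so it keeps directions of large variance
whether or not they discriminate.  This package implements a family of
supervised linear projections that use the class-conditional *first* and
*second* moments jointly while never requiring more dimensions than
samples, together with the machinery needed to study them: Gaussian
plug-in classifiers, an information-theoretic embedding score, exactly
parameterized simulation populations, and a cross-validated benchmark
harness.

## The projection family

Given samples `(x_i, y_i)` with `x_i in R^p` and `C` classes, let `mu_c` be
a per-class location estimate (the coordinate-wise class median by
default, the mean as the documented alternative) and let `M` be the
*class-centered* matrix whose `i`-th row is `x_i - mu_{y_i}`.  The
class-centered covariance `M'M/n` estimates the population covariance
without the between-class distortion that the pooled covariance carries.

A `d`-dimensional projection `W` is assembled from two blocks:

1. **Mean-difference block** (columns `1..C-1`).  For two classes, the
   single unit vector `(mu_1 - mu_0)/||mu_1 - mu_0||`.  For more classes,
   the top `C-1` left singular vectors of the prior-weighted deviation
   matrix `[sqrt(pi_c)(mu_c - mu_bar)]_c`, which reduces to the two-class
   difference and is invariant to class relabelling.
2. **Second-moment block** (remaining `d - C + 1` columns), one of:
   * top right singular vectors of `M` (**LOL**; with median locations the
     robust variant),
   * the union of each class's own singular vectors, globally sorted by
     singular value on the covariance scale (`sigma / sqrt(n_c)`), no
     per-class quota (**QOQ**; pair with QDA downstream),
   * seeded very sparse random-projection columns, entries `{-1, 0, +1}`
     with nonzero probability `c` (default `1/sqrt(p)`) scaled to unit
     expected norm (**LFL**).

Columns are unit-normalized but *not* orthogonalized against each other --
the construction concatenates, nothing more.  Requesting `d <= C-1` yields
a means-only projection, which is a legitimate member of the family (those
are its top embedding dimensions).

Baselines built on the same dataset type: PCA (pooled-centered singular
vectors), reduced-rank LDA (the second-moment block alone), dense/sparse
random projections, label-indicator CCA computed regularization-free
through the pseudo-inverse (which exhibits maximal data piling when
`p >= n` -- every training point of a class projects to one value), and
PLS via NIPALS-style deflation with the weights converted to rotations so
that plain `X @ W` reproduces the scores.

### Numerical conventions

* All exact eigenvector computations factor the `n x p` centered matrix
  (economy SVD); a `p x p` covariance is materialized only on explicit
  request.  Cost is `O(n p d)`-ish: linear in `p` at fixed `n, d`.
* Eigenvector sign: the entry of largest absolute value is made positive,
  ties to the lowest index.  Equal singular values keep the solver's
  stable order.  These are reproducibility conventions only.
* Covariance denominator `1/n` (maximum-likelihood form): only directions
  are consumed, so denominators cancel.
* **Nesting.** Every fit computes one full factorization and slices it, so
  truncating a `d`-dimensional model to `d' < d` is bit-identical to
  fitting at `d'`.  This required two deliberate choices: random-projection
  columns are seeded per column (child seed = (seed, column)), and PLS
  rotations are built by the forward recurrence
  `r_j = w_j - sum_{i<j} (p_i'w_j) r_i` rather than a `d x d` matrix
  inverse, with per-column norms computed on contiguous copies so the
  reduction order cannot depend on sibling columns.
* The randomized solver is a range-finder SVD with oversampling 10 and 2
  power iterations; it is documented as approximate and tested only for
  subspace agreement on well-separated spectra.
* Degenerate inputs raise typed errors: identical class locations (no
  mean-difference direction), zero cross-covariance (no PLS direction),
  `d` beyond the available rank.

## Classifiers

Plug-in Gaussian discriminants on the embedded data: LDA pools the
class-centered covariance, QDA keeps one per class; priors are training
proportions; prediction is `argmax_c log pi_c + log N(z; m_c, S_c)` with
ties resolved to the lower class index.  A ridge `1e-8 * trace(S)/d` is
always added because embedded dimensions can be collinear when `d`
approaches `n`.  For the two-class equal-covariance Gaussian population
the exact error is available in closed form from the Fisher SNR
`s = delta' Sigma^-1 delta` (equal priors: `Phi(-sqrt(s)/2)`).

## Chernoff-information evaluation

An embedding `W` is scored by the Chernoff information of the projected
population: `max_t in (0,1)` of

    C(t) = t(1-t)/2 * delta' Sigma_t^-1 delta
         + 1/2 ln[ det Sigma_t / (det Sigma_0^{1-t} det Sigma_1^t) ],

`Sigma_t = (1-t) Sigma_0 + t Sigma_1`, in nats, equal priors assumed.
This is the exponential decay rate of the Bayes error, hence the tightest
asymptotic criterion for "how classifiable is the projected problem".
Maximization uses a 99-point bracket followed by bounded scalar search to
`1e-10` in `t` (the divergence is smooth and in practice unimodal; the
grid guards rare multimodality).  For equal covariances the optimum is
`t* = 1/2` with value `s/8`.  Evaluation is population-level: projections
may be estimated from data, but the scored pair uses true parameters.
Finite-sample Chernoff estimation is out of scope.

## Simulation populations

Each named setting stores exact parameters (structured as per-class
diagonal variances plus an optional shared rotation), so Bayes error and
Chernoff references are computable, and sampling is `O(np)` plus one
rotation.  Defaults, chosen once to realize the qualitative physics each
setting exists to exhibit at the benchmark scale (`p = 1000`, `n = 100`):

* **trunk2** -- variances `sigma_j^2 = 100/sqrt(p+1-j)` (increasing to
  100), mean differences `delta_j = 8/sqrt(2j-1)` (decreasing), classes at
  `±delta/2`.  The discriminating coordinates are the *low*-variance ones.
  At this scale the mean-difference estimate is well conditioned (total
  estimation noise `4 sum_j sigma_j^2 / n ~ 250` against signal
  `||delta||^2 ~ 266`), so the mean-difference method is near-Bayes while
  the covariance-only method is at chance; a steeper variance profile
  (e.g. `sigma_j^2 = j`) at the same scale drowns the mean estimate and
  drives *every* method to chance, which is why this profile was chosen.
* **trunk3** -- trunk2 covariance, three equiprobable classes at `-delta`,
  `0`, `delta + rev(delta)`; the reversed pattern makes the second
  between-class direction informative.
* **rotated_trunk** -- trunk2 conjugated by a seeded Haar rotation
  (QR of a Gaussian matrix with sign-fixed diagonal); Fisher SNR invariant.
* **cigars** -- variance 100 on the first coordinate, 1 elsewhere; mean
  difference `(K, 0.1K/sqrt(j))` calibrated so `s = 9` (Bayes ~6.7%):
  signal aligned with maximal variance, easy for every method.
* **cross** -- equal means, covariances `I + 99 e_1 e_1'` vs
  `I + 99 e_2 e_2'`: only class-specific second moments separate the
  classes (Bayes error ~0.064 by Monte Carlo).
* **robust** -- trunk2 with fraction `rho = 0.2` of *training* draws given
  10x inflated noise (labels kept; test clean).
* **spherical** -- isotropic covariance, mean difference along a seeded
  random direction with `||delta||` calibrated to a 2% Bayes error
  (`s ~ 16.9`); the class-centered covariance carries no signal, so
  covariance-only projections are at chance by construction.

Monte-Carlo Bayes references (non-closed-form settings) use `1e5` draws
through the true-parameter Bayes rule and are cached per setting.

### What the generator does and does not emulate

These are exactly Gaussian, complete-data populations with known
parameters.  They exercise the geometry the methods are designed around --
wide data, informative vs uninformative variance directions, outliers,
class-specific covariance -- but not heavy tails beyond the contamination
mechanism, feature correlation structure of real imaging/omics data,
batch effects, or label noise.  Passing benchmarks here shows the
estimators behave as the theory predicts under their model, not that they
will win on any particular real dataset.

## Benchmark harness

Stratified k-fold (default `k = 5`, seeded).  Per fold and method a single
fit at `max(dims)` is truncated for every smaller dimension; embeddings
are always fit on the training folds.  The selected dimension minimizes
mean CV error (ties to the smallest `d`); Cohen's kappa
(`(p_o - p_e)/(1 - p_e)`) is computed at each method's *own* selected
dimension from the pooled out-of-fold confusion table.  Cross-dataset
comparison: effect size `kappa(reference) - kappa(method)` (negative
favors the method), within-dataset average ranks of selected-dimension
errors, and two-sided paired Wilcoxon signed-rank tests (exact null for
<= 25 datasets, zero differences dropped).

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run everything at the scales
the package itself documents: the held-out benchmark uses `p = 1000`
(trunk variants), `p = 100` (cross), `p = 3000` (spherical) with `n = 100`
training and 10,000 clean test draws per seed (20 seeds in the test suite,
10 in the acceptance script); Chernoff-ordering checks use 100 seeded
trials at `p = 120` (random rotated wide problems, `s = 16`) and `p = 300`
(trunk2), dimensions 1-10.  The spherical benchmark dimensionality was
chosen so that `p/n` exceeds the spiked-model detection threshold
`(s/4)^2 ~ 17.8`, the regime the setting is meant to probe.

## Known limitations

* Two of the documented benchmark expectations are not attainable as
  stated, and their checks are left failing deliberately.  (1) PCA is
  exactly rotation-equivariant, so a paired rotation of the trunk
  population cannot degrade it -- its error distribution on
  `rotated_trunk` is identical to `trunk2`.  (2) With the spherical
  setting calibrated to a 2% Bayes error, no `(p, n)` puts the
  mean-difference estimate within 0.02 of Bayes *and* PCA's first
  component below the detection threshold: the first needs
  `p/n <~ s^2/68`, the second `p/n >~ s^2/16`.  The remaining spherical
  claims (PCA worse than 0.4, covariance-only methods at chance) hold and
  are verified.
* Median-location projections are not rotation-equivariant (the
  coordinate-wise median is coordinate-bound); on Gaussian data they track
  the mean closely, which the rotated benchmark confirms empirically.
* Population Chernoff dominance of LOL over rrLDA/PCA is verified as a
  high-probability finite-sample property (>= 95/100 seeded trials), not
  re-proved.
* Out of scope: semi-external-memory/multi-core execution, sparse or
  penalized classifiers, real-data preprocessing pipelines, finite-sample
  Chernoff estimation.
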