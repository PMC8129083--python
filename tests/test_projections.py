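import numpy as np
import pytest

import xoxdr.projections as proj
from xoxdr import (
    DegenerateDataError,
    DimensionError,
    LabeledDataset,
    ParseError,
    XoxConfig,
    class_moments,
    delta_basis,
    fit_cca,
    fit_gaussian_classifier,
    fit_lfl,
    fit_lol,
    fit_pca,
    fit_pls,
    fit_qoq,
    fit_rp,
    fit_rrlda,
    fit_xox,
    load_projection,
    make_setting,
    nested_truncate,
    predict_classes,
    sample_from,
    save_projection,
    transform,
)
from conftest import random_dataset, sign_align


# ---------------------------------------------------------------------------
# moments


class TestClassMoments:
    def test_hand_means_and_centering(self, four_point):
        m = class_moments(four_point, "mean")
        np.testing.assert_array_equal(m.locations, [[0, 1], [4, 1]])
        np.testing.assert_array_equal(
            m.class_centered, [[0, -1], [0, 1], [0, -1], [0, 1]]
        )
        # mean-centering: per-class column sums vanish
        for c in range(2):
            np.testing.assert_allclose(
                m.per_class_centered(c).sum(axis=0), 0, atol=1e-12
            )

    def test_coordinatewise_median(self):
        X = np.array([[0.0, 0.0], [0.0, 2.0], [0.0, 100.0], [5.0, 5.0], [5.0, 6.0]])
        ds = LabeledDataset(X, np.array([0, 0, 0, 1, 1]), classes=np.arange(2))
        m = class_moments(ds, "median")
        np.testing.assert_array_equal(m.locations[0], [0.0, 2.0])

    def test_covariance_matches_dense_oracle(self, rng):
        ds = random_dataset(rng, n=30, p=8)
        m = class_moments(ds, "mean")
        M = m.class_centered
        np.testing.assert_allclose(m.cov_matrix(), M.T @ M / 30, atol=1e-12)

    def test_priors_sum_and_psd(self, rng):
        ds = random_dataset(rng, n=25, p=6, C=3)
        m = class_moments(ds, "median")
        assert m.priors.sum() == pytest.approx(1.0)
        eigvals = np.linalg.eigvalsh(m.cov_matrix())
        assert eigvals.min() >= -1e-12


class TestDeltaBasis:
    def test_two_class_direction(self, four_point):
        B = delta_basis(class_moments(four_point, "mean"))
        np.testing.assert_allclose(B, [[1.0], [0.0]], atol=1e-15)

    def test_identical_locations_raise(self):
        X = np.vstack([np.ones((3, 4)), np.ones((3, 4))])
        ds = LabeledDataset(X, np.repeat([0, 1], 3), classes=np.arange(2))
        with pytest.raises(DegenerateDataError, match="identical"):
            delta_basis(class_moments(ds, "mean"))

    def test_collinear_three_class_flags_degenerate_direction(self, rng):
        # three means exactly on the e1 axis: second direction is degenerate
        y = np.arange(30) % 3
        X = np.zeros((30, 5))
        X[:, 0] = y * 4.0
        ds = LabeledDataset(X, y, classes=np.arange(3))
        with pytest.warns(UserWarning, match="degenerate"):
            B = delta_basis(class_moments(ds, "mean"))
        assert B.shape == (5, 2)
        assert abs(B[0, 0]) > 0.99
        assert abs(B[:, 0] @ B[:, 1]) < 1e-8

    def test_multiclass_matches_weighted_svd_oracle(self, rng):
        ds = random_dataset(rng, n=40, p=10, C=3, shift=6.0)
        m = class_moments(ds, "mean")
        B = delta_basis(m)
        mu_bar = m.priors @ m.locations
        D = (np.sqrt(m.priors)[:, None] * (m.locations - mu_bar)).T
        U, s, _ = np.linalg.svd(D, full_matrices=False)
        oracle = U[:, :2]
        np.testing.assert_allclose(sign_align(B, oracle), B, atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(B, axis=0), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# the XOX family


class TestFitXox:
    def test_hand_case(self, four_point):
        m = fit_lol(four_point, 2, location="mean")
        np.testing.assert_allclose(m.W, np.eye(2), atol=1e-12)
        assert m.column_kind == ["mean_diff", "shared_eig"]

    def test_trunk3_top_dims_are_mean_differences(self):
        ds = sample_from(make_setting("trunk3", p=50), 60, seed=0)
        m = fit_lol(ds, 2)
        assert m.column_kind == ["mean_diff", "mean_diff"]

    def test_shared_eig_matches_dense_svd_oracle(self, rng):
        ds = random_dataset(rng, n=20, p=50)
        model = fit_lol(ds, 6, location="mean")
        M = class_moments(ds, "mean").class_centered
        _, _, Vt = np.linalg.svd(M, full_matrices=False)
        oracle = Vt[:5].T
        got = model.W[:, 1:]
        np.testing.assert_allclose(sign_align(got, oracle), got, atol=1e-8)

    def test_qoq_columns_follow_sorted_per_class_spectra(self, rng):
        ds = sample_from(make_setting("cross", p=20), 80, seed=3)
        model = fit_qoq(ds, 7, location="mean")
        m = class_moments(ds, "mean")
        # oracle: per-class singular values on the covariance scale
        vals = []
        for c in range(2):
            Mc = m.per_class_centered(c)
            s = np.linalg.svd(Mc, compute_uv=False) / np.sqrt(Mc.shape[0])
            vals += [(v, c, j) for j, v in enumerate(s)]
        vals.sort(key=lambda t: -t[0])
        expected_kinds = ["mean_diff"] + [f"class{c}_eig" for _, c, _ in vals[:6]]
        assert model.column_kind == expected_kinds
        # and the eigenvector columns match each class's dense SVD oracle
        for col, (_, c, j) in zip(model.W[:, 1:].T, vals[:6]):
            _, _, Vt = np.linalg.svd(m.per_class_centered(c), full_matrices=False)
            v = Vt[j]
            assert min(np.abs(col - v).max(), np.abs(col + v).max()) < 1e-8

    def test_d_up_to_cminus1_gives_means_only(self, four_point):
        m = fit_xox(four_point, 1, XoxConfig(location="mean"))
        assert m.column_kind == ["mean_diff"]

    def test_d_out_of_range(self, four_point):
        with pytest.raises(DimensionError):
            fit_lol(four_point, 3)

    def test_lfl_columns_are_sparse_sign_entries(self, rng):
        ds = random_dataset(rng, n=20, p=64)
        m = fit_lfl(ds, 5, seed=9)
        rp_cols = m.W[:, 1:]
        scale = 1.0 / np.sqrt(64 * (1 / np.sqrt(64)))
        vals = np.unique(np.round(np.abs(rp_cols) / scale, 12))
        assert set(vals.tolist()) <= {0.0, 1.0}

    def test_never_factorizes_p_by_p(self, rng, monkeypatch):
        """Scalability contract: only the n x p centered matrix is factorized."""
        shapes = []
        orig = proj._economy_svd

        def spy(M):
            shapes.append(M.shape)
            return orig(M)

        monkeypatch.setattr(proj, "_economy_svd", spy)
        ds = random_dataset(rng, n=15, p=3000)
        fit_lol(ds, 6, location="mean")
        assert all(min(s) <= 15 for s in shapes)

    def test_randomized_solver_close_on_separated_spectrum(self, rng):
        # well-separated spectrum: randomized range finder recovers the subspace
        scales = np.ones(200)
        scales[:3] = [30.0, 12.0, 5.0]
        X = rng.standard_normal((150, 200)) * scales
        ds = LabeledDataset(X, np.arange(150) % 2, classes=np.arange(2))
        exact = fit_lol(ds, 4, location="mean", solver="exact")
        rand = fit_lol(ds, 4, location="mean", solver="randomized", seed=0)
        # principal angles between eigenvector blocks
        sv = np.linalg.svd(exact.W[:, 1:].T @ rand.W[:, 1:], compute_uv=False)
        assert sv.min() > 0.99


# ---------------------------------------------------------------------------
# baselines


class TestPca:
    def test_rank_one_line(self, rng):
        t = rng.standard_normal(40)
        X = np.outer(t, [1.0, 1.0]) + 0.0
        ds = LabeledDataset(X, np.arange(40) % 2, classes=np.arange(2))
        m = fit_pca(ds, 1)
        np.testing.assert_allclose(np.abs(m.W[:, 0]), [1 / np.sqrt(2)] * 2, atol=1e-12)

    def test_global_shift_invariance(self, rng):
        ds = random_dataset(rng, n=25, p=10)
        shifted = LabeledDataset(ds.X + 7.5, ds.y, classes=ds.classes)
        np.testing.assert_allclose(fit_pca(ds, 4).W, fit_pca(shifted, 4).W, atol=1e-10)

    def test_matches_dense_svd_oracle(self, rng):
        ds = random_dataset(rng, n=30, p=12)
        m = fit_pca(ds, 4)
        _, _, Vt = np.linalg.svd(ds.X - ds.X.mean(axis=0), full_matrices=False)
        np.testing.assert_allclose(sign_align(m.W, Vt[:4].T), m.W, atol=1e-8)


class TestRrlda:
    def test_hand_case(self, four_point):
        m = fit_rrlda(four_point, 1)
        np.testing.assert_allclose(m.W, [[0.0], [1.0]], atol=1e-12)

    def test_class_shift_invariance(self, rng):
        ds = random_dataset(rng, n=30, p=8)
        X2 = ds.X.copy()
        X2[ds.y == 1] += 11.0
        shifted = LabeledDataset(X2, ds.y, classes=ds.classes)
        np.testing.assert_allclose(
            fit_rrlda(ds, 3).W, fit_rrlda(shifted, 3).W, atol=1e-8
        )

    def test_equals_lol_eigenvector_block(self, rng):
        ds = random_dataset(rng, n=25, p=15)
        lol = fit_lol(ds, 5, location="mean")
        rr = fit_rrlda(ds, 4)
        np.testing.assert_array_equal(lol.W[:, 1:], rr.W)


class TestRandomProjection:
    def test_seed_determinism(self):
        a, b = fit_rp(50, 4, seed=5), fit_rp(50, 4, seed=5)
        np.testing.assert_array_equal(a.W, b.W)
        assert np.abs(a.W - fit_rp(50, 4, seed=6).W).max() > 0

    def test_dense_sign_matrix_at_c_one(self):
        m = fit_rp(30, 3, seed=1, sparsity=1.0)
        np.testing.assert_allclose(np.abs(m.W) * np.sqrt(30), 1.0, atol=1e-12)

    def test_nonzero_fraction_binomial_bound(self):
        p = 10_000
        c = 1 / np.sqrt(p)
        m = fit_rp(p, 4, seed=2)
        frac = (m.W != 0).mean()
        sd = np.sqrt(c * (1 - c) / (p * 4))
        assert abs(frac - c) < 3 * sd

    def test_invalid_sparsity(self):
        with pytest.raises(ValueError):
            fit_rp(10, 2, seed=0, sparsity=0.0)


class TestCca:
    def test_data_piling_when_p_exceeds_n(self, rng):
        ds = random_dataset(rng, n=20, p=50)
        m = fit_cca(ds, 1)
        z = ds.X @ m.W[:, 0]
        spread = abs(z[ds.y == 1].mean() - z[ds.y == 0].mean())
        within = max(z[ds.y == 0].std(), z[ds.y == 1].std())
        assert within < 1e-8 * spread

    def test_matches_generalized_eigenproblem_oracle(self, rng):
        # p=2 << n: classic CCA via S_xx^-1 S_xy S_yy^-1 S_yx
        ds = random_dataset(rng, n=400, p=2, shift=4.0)
        m = fit_cca(ds, 1)
        Xc = ds.X - ds.X.mean(axis=0)
        Y = np.eye(2)[ds.y]
        Yc = Y - Y.mean(axis=0)
        Sxx, Sxy = Xc.T @ Xc, Xc.T @ Yc
        Syy = Yc.T @ Yc + 1e-12 * np.eye(2)
        Mmat = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
        w, V = np.linalg.eig(Mmat)
        v = np.real(V[:, np.argmax(np.real(w))])
        v /= np.linalg.norm(v)
        got = m.W[:, 0]
        assert min(np.abs(got - v).max(), np.abs(got + v).max()) < 1e-6

    def test_duplicating_samples_leaves_direction_unchanged(self, rng):
        ds = random_dataset(rng, n=50, p=4, shift=4.0)
        doubled = LabeledDataset(
            np.vstack([ds.X, ds.X]), np.concatenate([ds.y, ds.y]), classes=ds.classes
        )
        a, b = fit_cca(ds, 1).W[:, 0], fit_cca(doubled, 1).W[:, 0]
        assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_rank_limit(self, rng):
        ds = random_dataset(rng, n=30, p=10)
        with pytest.raises(DimensionError, match="rank"):
            fit_cca(ds, 2)


class TestPls:
    def test_first_direction_is_cross_covariance(self, rng):
        ds = random_dataset(rng, n=40, p=15, shift=4.0)
        m = fit_pls(ds, 1)
        ytilde = (ds.y - ds.y.mean())
        Xc = ds.X - ds.X.mean(axis=0)
        w = Xc.T @ ytilde
        w /= np.linalg.norm(w)
        got = m.W[:, 0]
        assert min(np.abs(got - w).max(), np.abs(got + w).max()) < 1e-10

    def test_scores_are_orthogonal(self, rng):
        ds = random_dataset(rng, n=40, p=15, shift=4.0)
        m = fit_pls(ds, 3)
        Z = (ds.X - ds.X.mean(axis=0)) @ m.W
        G = Z.T @ Z
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(G)).max()

    def test_beats_rrlda_on_trunk(self):
        # mean-difference methods find the signal; rrLDA is at chance
        setting = make_setting("trunk2", p=200)
        tr = sample_from(setting, 100, seed=4)
        te = sample_from(setting, 4000, seed=5, split="test")
        errs = {}
        for name, fit in (("pls", fit_pls), ("rrlda", fit_rrlda)):
            model = fit(tr, 3)
            clf = fit_gaussian_classifier(tr.X @ model.W, tr.y, "lda")
            errs[name] = (predict_classes(clf, te.X @ model.W) != te.y).mean()
        assert errs["pls"] < errs["rrlda"]


# ---------------------------------------------------------------------------
# transform / truncation / serialization


class TestTransform:
    def test_identity_block_selects_columns(self, rng):
        X = rng.standard_normal((6, 5))
        W = np.eye(5)[:, :3]
        model = proj.ProjectionModel(W, ["pca"] * 3, "pca")
        np.testing.assert_array_equal(transform(model, X), X[:, :3])
        np.testing.assert_array_equal(transform(model, np.zeros((4, 5))), np.zeros((4, 3)))

    def test_matches_naive_triple_loop(self, rng):
        X = rng.standard_normal((7, 6))
        W = rng.standard_normal((6, 3))
        model = proj.ProjectionModel(W, ["rp"] * 3, "rp")
        Z = transform(model, X)
        naive = np.zeros((7, 3))
        for i in range(7):
            for j in range(3):
                for k in range(6):
                    naive[i, j] += X[i, k] * W[k, j]
        np.testing.assert_allclose(Z, naive, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        model = proj.ProjectionModel(np.eye(4), ["pca"] * 4, "pca")
        with pytest.raises(DimensionError):
            transform(model, rng.standard_normal((3, 5)))


class TestNestedTruncate:
    @pytest.mark.parametrize("fit,kw", [
        (fit_lol, {"location": "median"}),
        (fit_lol, {"location": "mean"}),
        (fit_qoq, {"location": "mean"}),
        (fit_pca, {}),
        (fit_rrlda, {}),
        (fit_pls, {}),
    ])
    def test_truncation_equals_refit_bitwise(self, rng, fit, kw):
        ds = random_dataset(rng, n=30, p=50)
        big = fit(ds, 6, **kw)
        for d in (1, 3, 6):
            np.testing.assert_array_equal(
                nested_truncate(big, d).W, fit(ds, d, **kw).W
            )

    def test_lfl_nested_in_seed(self, rng):
        ds = random_dataset(rng, n=20, p=40)
        big = fit_lfl(ds, 8, seed=3)
        np.testing.assert_array_equal(nested_truncate(big, 4).W, fit_lfl(ds, 4, seed=3).W)

    def test_full_truncation_is_identity(self, four_point):
        m = fit_lol(four_point, 2, location="mean")
        np.testing.assert_array_equal(nested_truncate(m, 2).W, m.W)

    def test_truncate_to_class_count_leaves_mean_diffs(self, rng):
        ds = random_dataset(rng, n=30, p=20, C=3, shift=5.0)
        m = fit_lol(ds, 6)
        assert nested_truncate(m, 2).column_kind == ["mean_diff", "mean_diff"]

    def test_invalid_target(self, four_point):
        m = fit_lol(four_point, 2, location="mean")
        with pytest.raises(DimensionError):
            nested_truncate(m, 3)


class TestSerialization:
    def test_lossless_roundtrip(self, rng, tmp_path):
        ds = random_dataset(rng, n=20, p=30)
        m = fit_qoq(ds, 5, location="mean")
        path = str(tmp_path / "model.xox")
        save_projection(m, path)
        back = load_projection(path)
        np.testing.assert_array_equal(back.W, m.W)
        assert back.column_kind == m.column_kind
        assert back.method == m.method

    def test_loaded_model_transforms_identically(self, rng, tmp_path):
        ds = random_dataset(rng, n=15, p=12)
        m = fit_lol(ds, 4)
        path = str(tmp_path / "model.xox")
        save_projection(m, path)
        X = rng.standard_normal((8, 12))
        np.testing.assert_array_equal(
            transform(load_projection(path), X), transform(m, X)
        )

    def test_corrupted_file_is_a_parse_error(self, tmp_path):
        path = tmp_path / "junk.xox"
        path.write_text("not a model at all\n1 2 3\n")
        with pytest.raises(ParseError):
            load_projection(str(path))

    def test_version_mismatch(self, rng, tmp_path):
        ds = random_dataset(rng, n=10, p=5)
        path = str(tmp_path / "model.xox")
        save_projection(fit_pca(ds, 2), path)
        lines = open(path).read().splitlines()
        header = lines[0].replace('"version": 1', '"version": 99')
        (tmp_path / "model.xox").write_text("\n".join([header] + lines[1:]) + "\n")
        with pytest.raises(ParseError, match="version"):
            load_projection(path)

    def test_unwritable_path(self, four_point):
        m = fit_lol(four_point, 2, location="mean")
        with pytest.raises(IOError):
            save_projection(m, "/nonexistent-dir/model.xox")


# ---------------------------------------------------------------------------
# equivariance properties


class TestEquivariance:
    @pytest.mark.parametrize("fit,kw", [
        (fit_lol, {"location": "mean"}),
        (fit_pca, {}),
        (fit_rrlda, {}),
    ])
    def test_rotation_equivariance(self, rng, fit, kw):
        from xoxdr import haar_rotation

        ds = random_dataset(rng, n=30, p=40)
        Q = haar_rotation(40, seed=11)
        rotated = LabeledDataset(ds.X @ Q.T, ds.y, classes=ds.classes)
        W0 = fit(ds, 5, **kw).W
        W1 = fit(rotated, 5, **kw).W
        np.testing.assert_allclose(sign_align(Q @ W0, W1), Q @ W0, atol=1e-8)

    def test_unit_norm_invariant(self, rng):
        ds = random_dataset(rng, n=20, p=30, C=3, shift=4.0)
        for model in (fit_lol(ds, 5), fit_qoq(ds, 5), fit_pca(ds, 4),
                      fit_rrlda(ds, 4), fit_cca(ds, 2), fit_pls(ds, 3)):
            np.testing.assert_allclose(
                np.linalg.norm(model.W, axis=0), 1.0, atol=1e-8,
                err_msg=model.method,
            )
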