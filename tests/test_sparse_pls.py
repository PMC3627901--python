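import numpy as np
import pytest

from mlspls import (
    dummy_matrix,
    fit_spls,
    fit_splsda,
    predict_classes,
    selected_features,
    standardize,
)

from conftest import make_crossover


class TestStandardize:
    def test_two_point_column(self):
        xs, stats = standardize(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(
            xs[:, 0], [-0.70710678, 0.70710678], atol=1e-8
        )
        assert stats.sd[0] == pytest.approx(np.sqrt(2))  # N-1 denominator

    def test_idempotent(self, rng):
        xs, _ = standardize(rng.normal(size=(10, 4)))
        xs2, _ = standardize(xs)
        np.testing.assert_allclose(xs2, xs, atol=1e-10)

    def test_constant_column_dropped(self, rng):
        x = rng.normal(size=(8, 3))
        x[:, 1] = 5.0
        xs, stats = standardize(x)
        assert xs.shape[1] == 2
        assert stats.n_kept == 2
        assert not stats.kept[1]

    def test_all_constant_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize(np.ones((5, 3)))


class TestDummyMatrix:
    def test_basic_and_level_order(self):
        y = dummy_matrix(["A", "A", "B"])
        assert list(y.columns) == ["A", "B"]
        np.testing.assert_array_equal(y.to_numpy(), [[1, 0], [1, 0], [0, 1]])

    def test_four_groups_repeated(self):
        y = dummy_matrix(["A", "B", "C", "D"] * 12)
        assert y.shape == (48, 4)
        np.testing.assert_array_equal(y.sum(axis=0), [12, 12, 12, 12])

    def test_row_permutation_equivariance(self, rng):
        groups = ["A", "B", "C"] * 4
        perm = rng.permutation(len(groups))
        y = dummy_matrix(groups)
        yp = dummy_matrix([groups[i] for i in perm])
        # align columns by level name: rows then just permute
        np.testing.assert_array_equal(
            yp[list(y.columns)].to_numpy(), y.to_numpy()[perm]
        )

    def test_single_level_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            dummy_matrix(["A", "A", "A"])


def _svd_leading(m):
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    return u[:, 0], vt[0, :], s[0]


def _sign_align(a, ref):
    return a * np.sign(np.dot(a, ref) or 1.0)


class TestFitSpls:
    def test_dense_matches_svd_oracle(self, rng):
        x = rng.normal(size=(10, 6))
        z = rng.normal(size=(10, 4))
        model = fit_spls(x, z, 1, keepX=[6], keepZ=[4])
        xs, _ = standardize(x)
        zs, _ = standardize(z)
        u_ref, v_ref, s1 = _svd_leading(xs.T @ zs)
        np.testing.assert_allclose(
            _sign_align(model.x_loadings[:, 0], u_ref), u_ref, atol=1e-6
        )
        np.testing.assert_allclose(
            _sign_align(model.z_loadings[:, 0], v_ref), v_ref, atol=1e-6
        )
        assert model.score_covariances()[0] == pytest.approx(s1 / 9, rel=1e-6)

    def test_keepx_one_matches_bruteforce(self, rng):
        # best single X feature maximizes the norm of its cross-product row
        x = rng.normal(size=(8, 5))
        z = rng.normal(size=(8, 3))
        model = fit_spls(x, z, 1, keepX=[1], keepZ=[3])
        u = model.x_loadings[:, 0]
        assert np.count_nonzero(u) == 1
        xs, _ = standardize(x)
        zs, _ = standardize(z)
        row_norms = np.linalg.norm(xs.T @ zs, axis=1)
        assert int(np.argmax(np.abs(u))) == int(np.argmax(row_norms))

    def test_self_integration_recovers_pca(self, rng):
        x = rng.normal(size=(12, 5)) @ np.diag([3, 2, 1, 1, 1])
        model = fit_spls(x, x, 1)
        xs, _ = standardize(x)
        _, _, vt = np.linalg.svd(xs, full_matrices=False)
        pc1 = xs @ vt[0]
        xi = model.x_scores[:, 0]
        corr = np.corrcoef(xi, pc1)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-8)

    def test_row_mismatch_error(self, rng):
        with pytest.raises(ValueError, match="rows"):
            fit_spls(rng.normal(size=(8, 3)), rng.normal(size=(7, 3)))

    def test_keep_out_of_range(self, rng):
        x, z = rng.normal(size=(8, 4)), rng.normal(size=(8, 3))
        with pytest.raises(ValueError, match="keepX"):
            fit_spls(x, z, 1, keepX=[9])


class TestFitSplsda:
    def test_separable_toy_selects_informative_feature(self, separable_toy):
        x, d = separable_toy
        from mlspls import within_matrix

        xw = within_matrix(x, d)
        model = fit_splsda(xw, d.condition, 1, keepX=[1])
        sel = selected_features(model)
        assert sel["per_dimension"][0] == ["g1"]

    def test_dense_matches_svd_of_cross_product(self, rng):
        x = rng.normal(size=(12, 6))
        groups = ["A", "B", "C"] * 4
        model = fit_splsda(x, groups, 1)
        xs, _ = standardize(x)
        ys, _ = standardize(dummy_matrix(groups).to_numpy())
        u_ref, _, _ = _svd_leading(xs.T @ ys)
        np.testing.assert_allclose(
            _sign_align(model.x_loadings[:, 0], u_ref), u_ref, atol=1e-6
        )

    def test_two_group_label_order_symmetry(self, rng):
        x = rng.normal(size=(10, 4))
        groups = ["A", "B"] * 5
        swap = {"A": "B", "B": "A"}
        m1 = fit_splsda(x, groups, 1)
        m2 = fit_splsda(x, [swap[g] for g in groups], 1)
        # the discriminant direction is the same up to sign ...
        dot = abs(np.dot(m1.x_loadings[:, 0], m2.x_loadings[:, 0]))
        assert dot == pytest.approx(1.0, abs=1e-6)
        # ... and the class assignments are label-consistent
        p1, _ = predict_classes(m1, x)
        p2, _ = predict_classes(m2, x)
        assert [swap[g] for g in p1] == p2

    def test_h_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="n_components"):
            fit_splsda(rng.normal(size=(6, 3)), ["A", "B", "C"] * 2, 6)

    def test_keepx_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="keepX"):
            fit_splsda(rng.normal(size=(8, 4)), ["A", "B"] * 4, 1, keepX=[2, 2])


class TestPredict:
    def test_training_rows_of_separable_toy(self, separable_toy):
        x, d = separable_toy
        from mlspls import within_matrix

        xw = within_matrix(x, d)
        model = fit_splsda(xw, d.condition, 1, keepX=[1])
        pred, _ = predict_classes(model, xw)
        assert pred == list(d.condition)

    def test_zero_input_ties_to_first_level(self, rng):
        x = rng.normal(size=(12, 4))
        groups = ["A", "B", "C"] * 4
        model = fit_splsda(x, groups, 2)
        mean_row = x.mean(axis=0)
        pred, yhat = predict_classes(model, mean_row)
        # balanced groups: the prediction reduces to the class proportions
        np.testing.assert_allclose(yhat[0], 1 / 3, atol=1e-8)
        assert pred == ["A"]

    def test_feature_count_mismatch(self, rng):
        model = fit_splsda(rng.normal(size=(8, 4)), ["A", "B"] * 4, 1)
        with pytest.raises(ValueError, match="features"):
            predict_classes(model, rng.normal(size=(2, 7)))

    def test_permuted_labels_near_chance(self, rng):
        # small two-group null: held-out accuracy should hover at chance
        errs = []
        for rep in range(20):
            x, d = make_crossover(
                6, ("A", "B"), 20, np.random.default_rng(rep), noise_sd=1.0
            )
            from mlspls import subject_cv_error

            errs.append(subject_cv_error(x, d, 5, 1, multilevel=True)[0])
        assert np.mean(errs) == pytest.approx(0.5, abs=0.15)


class TestModelInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_norms_sparsity_orthogonality_deflation(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(15, 12))
        z = rng.normal(size=(15, 6))
        keepx, keepz = [5, 3, 7], [4, 2, 6]
        model = fit_spls(x, z, 3, keepX=keepx, keepZ=keepz)
        for h in range(3):
            u, v = model.x_loadings[:, h], model.z_loadings[:, h]
            assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-8)
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-8)
            assert np.count_nonzero(u) == keepx[h]
            assert np.count_nonzero(v) == keepz[h]
            # sign convention: largest-|entry| coordinate positive
            assert u[np.argmax(np.abs(u))] > 0
        xi = model.x_scores
        gram = xi.T @ xi
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-6 * np.max(np.diag(gram))

    def test_deflation_identity(self, rng):
        x = rng.normal(size=(10, 8))
        z = rng.normal(size=(10, 5))
        model = fit_spls(x, z, 2, keepX=[8, 8], keepZ=[5, 5])
        xs, _ = standardize(x)
        u1 = model.x_loadings[:, 0]
        xi1 = xs @ u1
        c1 = xs.T @ xi1 / (xi1 @ xi1)
        x1 = xs - np.outer(xi1, c1)
        np.testing.assert_allclose(model.x_regression[:, 0], c1, atol=1e-8)
        # second-dimension score comes from the deflated matrix
        np.testing.assert_allclose(
            model.x_scores[:, 1], x1 @ model.x_loadings[:, 1], atol=1e-8
        )

    def test_beta_reproduces_fitted_values(self, rng):
        x = rng.normal(size=(12, 7))
        groups = ["A", "B", "C"] * 4
        model = fit_splsda(x, groups, 2, keepX=[4, 4])
        xs, _ = standardize(x)
        fitted = model.x_scores @ model.z_regression.T  # sum_h xi_h e_h'
        np.testing.assert_allclose(xs @ model.beta, fitted, atol=1e-8)

    def test_in_sample_classes_consistent(self, rng):
        x, d = make_crossover(
            5, ("A", "B", "C"), 30, rng, noise_sd=0.2,
            condition_effects=np.repeat(np.eye(3) * 2.0, 10, axis=1),
        )
        model = fit_splsda(x.values, d.condition, 2)
        pred, _ = predict_classes(model, x.values)
        fitted_again, _ = predict_classes(model, x.values)
        assert pred == fitted_again


class TestSelectedFeatures:
    def test_requested_sizes_and_union(self):
        from mlspls import SimulationSpec, simulate_dataset, within_matrix

        x, d, _ = simulate_dataset(SimulationSpec(seed=5))
        xw = within_matrix(x, d)
        model = fit_splsda(xw, d.condition, 3, keepX=[30, 137, 123])
        sel = selected_features(model)
        assert [len(s) for s in sel["per_dimension"]] == [30, 137, 123]
        assert len(sel["union"]) <= 290

    def test_all_zero_dimension_gives_empty_list(self, rng):
        model = fit_splsda(rng.normal(size=(8, 4)), ["A", "B"] * 4, 1)
        model.x_loadings[:, 0] = 0.0
        sel = selected_features(model)
        assert sel["per_dimension"][0] == []


class TestMixOmicsCrossCheck:
    """Loadings frozen from an independent reference fit (mixOmics 6.26,
    R/Bioconductor) on the same deterministically generated 12x8 / 12x5
    fixture; agreement is up to a per-component sign and the iteration
    tolerance."""

    def _fixture(self):
        rng = np.random.default_rng(2024)
        x = rng.standard_normal((12, 8))
        z = rng.standard_normal((12, 5))
        groups = ["A", "B", "C"] * 4
        return x, z, groups

    def test_splsda_loadings(self):
        x, _, groups = self._fixture()
        model = fit_splsda(x, groups, 2, keepX=[3, 4])
        ref = np.zeros((8, 2))
        ref[[1, 2, 7], 0] = [-0.2314478, -0.8616067, -0.4517365]
        ref[[1, 4, 6, 7], 1] = [-0.61714231, 0.41616344, 0.09659279, 0.66076713]
        for h in range(2):
            got = _sign_align(model.x_loadings[:, h], ref[:, h])
            np.testing.assert_allclose(got, ref[:, h], atol=2e-3)

    def test_spls_mode_a_loadings(self):
        x, z, _ = self._fixture()
        model = fit_spls(x, z, 2, keepX=[3, 3], keepZ=[2, 2])
        ref_u = np.zeros((8, 2))
        ref_u[[0, 1, 2], 0] = [-0.3440677, -0.6437748, -0.6834994]
        ref_u[[4, 5, 6], 1] = [-0.64297059, 0.76238392, 0.07320914]
        ref_v = np.zeros((5, 2))
        ref_v[[1, 2], 0] = [-0.9788773, -0.2044483]
        ref_v[[0, 4], 1] = [-0.5410626, -0.8409823]
        for h in range(2):
            sign = np.sign(np.dot(model.x_loadings[:, h], ref_u[:, h]))
            np.testing.assert_allclose(
                sign * model.x_loadings[:, h], ref_u[:, h], atol=2e-3
            )
            np.testing.assert_allclose(
                sign * model.z_loadings[:, h], ref_v[:, h], atol=2e-3
            )
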