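import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nanoqsar as nq
from nanoqsar.gp import HyperGrid, KernelConfig

from conftest import random_descriptors

vec3 = st.lists(
    st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=3, max_size=3
).map(np.array)


def dense_gp_mean(X, y, Xq, cfg, s2):
    """Independent closed-form oracle for the predictive mean: direct dense
    solve of the amplitude-scaled GP equations (no Cholesky, no caching)."""
    ym, sd = y.mean(), y.std()
    K = nq.kernel_matrix(X, X, cfg)
    Ks = nq.kernel_matrix(Xq, X, cfg)
    inner = np.linalg.solve(sd**2 * K + s2 * np.eye(len(y)), y - ym)
    return sd**2 * Ks @ inner + ym


class TestStandardization:
    def test_training_columns_centered_and_scaled(self, table3):
        tr = table3.subset(table3.training_mask)
        params = nq.standardize_fit(tr.descriptor_matrix())
        Z = nq.standardize_apply(params, tr.descriptor_matrix())
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_test_rows_not_recentered(self, table3):
        tr = table3.subset(table3.training_mask)
        te = table3.subset(table3.test_mask)
        params = nq.standardize_fit(tr.descriptor_matrix())
        Zt = nq.standardize_apply(params, te.descriptor_matrix())
        assert np.abs(Zt.mean(axis=0)).max() > 1e-6

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(100, 20, (8, 3))
        params = nq.standardize_fit(X)
        np.testing.assert_allclose(
            nq.standardize_invert(params, nq.standardize_apply(params, X)),
            X, atol=1e-12 * 100)

    def test_constant_column_rejected(self):
        X = np.ones((5, 2))
        X[:, 0] = np.arange(5)
        with pytest.raises(ValueError, match="zero-variance"):
            nq.standardize_fit(X)


class TestKernel:
    @given(x=vec3)
    @settings(deadline=None, max_examples=50)
    def test_normalized_diagonal_is_one(self, x):
        cfg = KernelConfig(degree=3, include_lower_order=True, normalize=True)
        assert nq.kernel_value(x, x, cfg) == pytest.approx(1.0, abs=1e-12)

    @given(x=vec3, z=vec3)
    @settings(deadline=None, max_examples=50)
    def test_symmetry_and_cauchy_schwarz(self, x, z):
        cfg = KernelConfig(degree=2, include_lower_order=True, normalize=True)
        kxz = nq.kernel_value(x, z, cfg)
        assert kxz == pytest.approx(nq.kernel_value(z, x, cfg), abs=1e-12)
        assert abs(kxz) <= 1.0 + 1e-12

    def test_degree1_unnormalized_is_dot_product(self):
        cfg = KernelConfig(degree=1, include_lower_order=False, normalize=False)
        x, z = np.array([1.0, 2.0, -1.0]), np.array([0.5, -1.0, 3.0])
        assert nq.kernel_value(x, z, cfg) == pytest.approx(x @ z)

    def test_zero_vector_with_c0_rejected(self):
        cfg = KernelConfig(degree=2, include_lower_order=False, normalize=True)
        with pytest.raises(ValueError, match="self-similarity"):
            nq.kernel_value(np.zeros(3), np.ones(3), cfg)

    def test_training_kernel_psd(self, table3):
        """Eigendecomposition oracle: the 12x12 training kernel matrix is
        symmetric positive semidefinite before any jitter."""
        tr = table3.subset(table3.training_mask)
        params = nq.standardize_fit(tr.descriptor_matrix())
        Z = nq.standardize_apply(params, tr.descriptor_matrix())
        for degree in (1, 2, 3):
            K = nq.kernel_matrix(Z, Z, KernelConfig(degree=degree))
            np.testing.assert_allclose(K, K.T, atol=1e-12)
            assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            nq.kernel_value(np.ones(3), np.ones(4), KernelConfig())


class TestGPFitPredict:
    def test_zero_noise_interpolates(self, table3):
        # degree 3 with lower-order terms spans 20 dimensions in 3-D input
        # space, enough to interpolate the 12 training rows
        tr = table3.subset(table3.training_mask)
        model = nq.gp_fit(tr.descriptor_matrix(), tr.ec50, KernelConfig(degree=3),
                          1e-10)
        pred, _ = nq.gp_predict(model, tr.descriptor_matrix())
        np.testing.assert_allclose(pred, tr.ec50, rtol=1e-4)

    def test_degree1_matches_linear_closed_form(self):
        """100 seeded 5x3 problems: GP mean equals the kernel-ridge/linear
        closed form evaluated by an independent dense solve."""
        cfg = KernelConfig(degree=1, include_lower_order=False, normalize=False)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (5, 3))
            y = rng.normal(150, 40, 5)
            Xq = rng.normal(0, 1, (4, 3))
            scaler = nq.standardize_fit(X)
            Z = nq.standardize_apply(scaler, X)
            Zq = nq.standardize_apply(scaler, Xq)
            model = nq.gp_fit(Z, y, cfg, 0.5, scaler=scaler, standardized=True)
            ours, _ = nq.gp_predict(model, Zq, standardized=True)
            oracle = dense_gp_mean(Z, y, Zq, cfg, 0.5)
            np.testing.assert_allclose(ours, oracle, rtol=1e-8)

    def test_normalized_kernel_matches_dense_oracle(self):
        cfg = KernelConfig(degree=3, include_lower_order=True, normalize=True)
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            X = random_descriptors(rng, 8)
            y = rng.normal(150, 40, 8)
            Xq = random_descriptors(rng, 3)
            model = nq.gp_fit(X, y, cfg, 10.0)
            ours, _ = nq.gp_predict(model, Xq)
            Z = nq.standardize_apply(model.scaler, X)
            Zq = nq.standardize_apply(model.scaler, Xq)
            oracle = dense_gp_mean(Z, y, Zq, cfg, 10.0)
            np.testing.assert_allclose(ours, oracle, rtol=1e-8)

    def test_matches_sklearn_kernel_ridge(self):
        """Cross-check against an independent solver: kernel ridge with a
        precomputed amplitude-scaled Gram matrix gives the same mean."""
        from sklearn.kernel_ridge import KernelRidge

        cfg = KernelConfig(degree=2, include_lower_order=True, normalize=True)
        rng = np.random.default_rng(5)
        X = random_descriptors(rng, 10)
        y = rng.normal(150, 40, 10)
        Xq = random_descriptors(rng, 4)
        s2 = 25.0
        model = nq.gp_fit(X, y, cfg, s2)
        ours, _ = nq.gp_predict(model, Xq)
        Z = nq.standardize_apply(model.scaler, X)
        Zq = nq.standardize_apply(model.scaler, Xq)
        amp = y.std() ** 2
        kr = KernelRidge(alpha=s2, kernel="precomputed")
        kr.fit(amp * nq.kernel_matrix(Z, Z, cfg), y - y.mean())
        theirs = kr.predict(amp * nq.kernel_matrix(Zq, Z, cfg)) + y.mean()
        np.testing.assert_allclose(ours, theirs, rtol=1e-8)

    def test_permutation_invariance(self, signal_table):
        tr = signal_table.subset(signal_table.training_mask)
        cfg = KernelConfig(degree=2)
        X, y = tr.descriptor_matrix(), tr.ec50
        perm = np.random.default_rng(3).permutation(len(y))
        m1 = nq.gp_fit(X, y, cfg, 10.0)
        m2 = nq.gp_fit(X[perm], y[perm], cfg, 10.0)
        q = X[:4]
        p1, v1 = nq.gp_predict(m1, q)
        p2, v2 = nq.gp_predict(m2, q)
        np.testing.assert_allclose(p1, p2, atol=1e-10 * np.abs(p1).max())
        np.testing.assert_allclose(v1, v2, atol=1e-8)

    def test_variance_properties(self, signal_table):
        tr = signal_table.subset(signal_table.training_mask)
        s2 = 4.0
        model = nq.gp_fit(tr.descriptor_matrix(), tr.ec50, KernelConfig(degree=2), s2)
        pred, var = nq.gp_predict(model, tr.descriptor_matrix())
        assert np.all(var >= 0)
        assert np.all(var <= s2 + 1e-8)

    def test_duplicated_queries_identical(self, signal_model, signal_table):
        model, _, _ = signal_model
        q = signal_table.descriptor_matrix()[:1]
        pred, var = nq.gp_predict(model, np.vstack([q, q]))
        assert pred[0] == pred[1] and var[0] == var[1]

    def test_training_rmse_monotone_in_noise(self, signal_table):
        tr = signal_table.subset(signal_table.training_mask)
        cfg = KernelConfig(degree=2)
        rmses = []
        for s2 in [1e-8, 1e-2, 1.0, 100.0, 1e4]:
            m = nq.gp_fit(tr.descriptor_matrix(), tr.ec50, cfg, s2)
            pred, _ = nq.gp_predict(m, tr.descriptor_matrix())
            rmses.append(nq.rmse(tr.ec50, pred))
        # tolerance covers round-off at the rank-deficiency floor
        assert all(a <= b * (1 + 1e-5) for a, b in zip(rmses, rmses[1:]))

    def test_negative_noise_rejected(self, signal_table):
        tr = signal_table.subset(signal_table.training_mask)
        with pytest.raises(ValueError):
            nq.gp_fit(tr.descriptor_matrix(), tr.ec50, KernelConfig(), -1.0)

    def test_duplicate_rows_zero_noise_jitter_rescues(self):
        rng = np.random.default_rng(8)
        X = random_descriptors(rng, 6)
        X[3] = X[0]  # singular kernel matrix at sigma^2 = 0
        y = rng.normal(150, 30, 6)
        y[3] = y[0]
        model = nq.gp_fit(X, y, KernelConfig(degree=1), 0.0)
        assert model.jitter > 0


class TestHyperparameterSelection:
    def test_single_point_grid_returned(self, signal_table):
        tr = signal_table.subset(signal_table.training_mask)
        grid = HyperGrid(degrees=(2,), offsets=(1,), noise_ratios=(0.01,))
        cfg, s2, _ = nq.select_hyperparameters(tr.descriptor_matrix(), tr.ec50, grid)
        assert cfg.degree == 2 and cfg.include_lower_order
        assert s2 == pytest.approx(0.01 * np.var(tr.ec50))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            HyperGrid(degrees=())

    def test_degree2_truth_recovered(self):
        """Self-consistency: on noise-free draws from a degree-2 normalized
        kernel GP, the grid search picks degree 2 in >= 90% of replicates."""
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            X = random_descriptors(rng, 16)
            scaler = nq.standardize_fit(X)
            Z = nq.standardize_apply(scaler, X)
            K = nq.kernel_matrix(Z, Z, KernelConfig(degree=2))
            L = np.linalg.cholesky(K + 1e-10 * np.eye(16))
            y = 150.0 + 40.0 * (L @ rng.normal(0, 1, 16))
            cfg, _, _ = nq.select_hyperparameters(X, y)
            hits += cfg.degree == 2
        assert hits >= 0.9 * n_rep

    def test_selection_invariant_to_row_order(self, signal_table):
        tr = signal_table.subset(signal_table.training_mask)
        X, y = tr.descriptor_matrix(), tr.ec50
        perm = np.random.default_rng(1).permutation(len(y))
        a = nq.select_hyperparameters(X, y)
        b = nq.select_hyperparameters(X[perm], y[perm])
        assert a[0] == b[0]
        assert a[1] == pytest.approx(b[1], rel=1e-12)


class TestSerialization:
    def test_json_round_trip_bit_exact(self, signal_model):
        model, _, _ = signal_model
        restored = nq.model_from_json(nq.model_to_json(model))
        assert restored.kernel == model.kernel
        assert restored.noise_variance == model.noise_variance
        assert restored.target_mean == model.target_mean
        assert restored.target_sd == model.target_sd
        for attr in ("train_inputs", "train_targets", "weights", "cholesky_lower"):
            np.testing.assert_array_equal(getattr(restored, attr),
                                          getattr(model, attr))
        q = model.train_inputs[:2]
        np.testing.assert_array_equal(
            nq.gp_predict(model, q, standardized=True)[0],
            nq.gp_predict(restored, q, standardized=True)[0])

    def test_version_guard(self, signal_model):
        import json
        model, _, _ = signal_model
        doc = json.loads(nq.model_to_json(model))
        doc["format_version"] = 999
        with pytest.raises(ValueError, match="version"):
            nq.model_from_json(json.dumps(doc))
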