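"""Feature assembly, standardization, GNLL network and the T1 attack."""

import warnings

import numpy as np
import pytest

from deepcestph import (HeteroscedasticMLP, NetConfig, assemble_features,
                        gnll_loss, predict, predict_rows, standardize,
                        t1_attack, train)
from deepcestph.model import (StandardizationStats, load_checkpoint,
                              save_checkpoint)
from deepcestph.processing import ZSpectrumVolume


def _toy_inputs(n=4, noff=7, seed=0):
    rng = np.random.default_rng(seed)
    shape = (n, n, 2)
    z = rng.uniform(0.3, 1.0, shape + (noff,))
    zvol = ZSpectrumVolume(np.linspace(-3, 3, noff), z, (3, 3, 4),
                           np.ones(shape, bool))
    asym = rng.normal(0, 0.01, shape + (11,))
    qt1 = rng.uniform(0.8, 2.0, shape)
    mask = np.ones(shape, bool)
    return zvol, asym, qt1, mask


class TestAssembleFeatures:
    def test_row_count_equals_mask(self):
        zvol, asym, qt1, mask = _toy_inputs()
        mask[:] = False
        mask.reshape(-1)[:10] = True
        table = assemble_features(zvol, asym, qt1, mask)
        assert table.X.shape == (10, 7 + 11 + 1)

    def test_nan_t1_drops_only_that_voxel(self):
        zvol, asym, qt1, mask = _toy_inputs()
        qt1[0, 0, 0] = np.nan
        table = assemble_features(zvol, asym, qt1, mask)
        assert table.n_dropped == 1
        assert table.X.shape[0] == mask.sum() - 1
        assert np.isfinite(table.X).all()

    def test_asym_block_width_is_11(self):
        zvol, asym, qt1, mask = _toy_inputs()
        table = assemble_features(zvol, asym, qt1, mask)
        assert table.X.shape[1] - zvol.offsets.size - 1 == 11


class TestStandardize:
    def test_train_columns_become_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3, 2, (500, 4))
        Xs, _, stats = standardize(X)
        assert np.allclose(Xs.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Xs.std(axis=0), 1.0, atol=1e-9)

    def test_apply_then_invert_is_identity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 5, (100, 3))
        _, _, stats = standardize(X)
        Xs, _, _ = standardize(X, stats=stats)
        back = Xs * stats.feature_sd + stats.feature_mean
        assert np.allclose(back, X, atol=1e-12)

    def test_constant_column_pinned_with_warning(self):
        X = np.ones((50, 2))
        X[:, 1] = np.arange(50)
        with pytest.warns(UserWarning):
            Xs, _, stats = standardize(X)
        assert np.all(Xs[:, 0] == 0.0)
        assert stats.feature_sd[0] == 1.0


class TestGnll:
    def test_zero_at_perfect_prediction_unit_variance(self):
        assert gnll_loss(np.array([1.0]), np.array([1.0]), np.array([1.0])) == 0.0

    def test_floor_is_minimizer_for_zero_residual(self):
        y = np.array([2.0])
        mu = np.array([2.0])
        floor = 1e-6
        at_floor = gnll_loss(mu, np.array([floor]), y, floor)
        above = gnll_loss(mu, np.array([1e-3]), y, floor)
        assert at_floor < above

    def test_analytic_variance_minimizer(self):
        """For fixed residual the optimum variance equals the squared error."""
        mu, y = np.array([0.0]), np.array([0.5])
        s_star = (y - mu) ** 2
        grid = np.linspace(0.5 * s_star, 2.0 * s_star, 101)
        losses = [gnll_loss(mu, np.array([s]), y) for s in grid]
        assert abs(grid[int(np.argmin(losses))] - s_star) < 0.02 * s_star

    def test_gradient_matches_finite_differences(self):
        """Central-difference check of every parameter gradient.

        Biases are nudged off zero first: with zero biases a fully dead
        ReLU row places a pre-activation exactly on the kink, where the
        subgradient and a finite difference legitimately disagree.
        """
        rng = np.random.default_rng(0)
        net = HeteroscedasticMLP(5, (4, 3), seed=1)
        for b in (*net.b, net.bm, net.bs):
            b += rng.normal(0.0, 0.05, b.shape)
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        _, grads = net._grads(X, y)

        def loss():
            mu, s2, _, _ = net._forward(X)
            return float(np.mean(0.5 * (np.log(s2) + (mu - y) ** 2 / s2)))

        eps = 1e-6
        for p, g in zip(net._params(), grads):
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss()
                p[idx] = orig - eps
                lm = loss()
                p[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert fd == pytest.approx(g[idx], rel=1e-5, abs=1e-8)


class TestTraining:
    def test_same_seed_identical_weights_and_curves(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(400, 6))
        y = X[:, 0] * 0.1 + 7.0
        cfg = NetConfig(seed=11, epochs=5, batch_size=64)
        a = train(X, y, cfg)
        b = train(X, y, cfg)
        for wa, wb in zip(a.model._params(), b.model._params()):
            assert np.array_equal(wa, wb)
        assert a.history == b.history

    def test_learns_noiseless_affine_map(self):
        """Validation RMSE < 0.005 within 200 epochs on a linear toy."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(2000, 4))
        y = 7.0 + 0.05 * X[:, 2]
        cfg = NetConfig(seed=2, epochs=200, batch_size=256)
        fit = train(X, y, cfg)
        assert fit.val_rmse < 0.005

    def test_divergence_aborts_with_diagnostics(self):
        """A non-finite loss aborts the optimizer step instead of silently
        corrupting the weights."""
        net = HeteroscedasticMLP(2, (4,), seed=0)
        X = np.array([[np.inf, 1.0]])
        with np.errstate(invalid="ignore"), pytest.raises(FloatingPointError):
            net.adam_step(X, np.array([0.0]))

    def test_nonfinite_targets_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        y = np.full(50, np.nan)
        with pytest.raises(ValueError):
            train(X, y, NetConfig(epochs=1))


class TestPrediction:
    def _trained(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(600, 19))
        y = 7.0 + 0.05 * X[:, 0] + rng.normal(0, 0.01, 600)
        fit = train(X, y, NetConfig(seed=1, epochs=30, batch_size=128))
        return fit, X, y

    def test_sigma_respects_variance_floor(self):
        fit, X, _ = self._trained()
        _, sig = predict_rows(fit.model, fit.stats, X)
        assert np.all(sig >= np.sqrt(fit.config.variance_floor)
                      * fit.stats.target_sd - 1e-15)

    def test_prediction_map_masks_and_orders(self):
        zvol_shape = (3, 3, 2)
        rng = np.random.default_rng(0)
        from deepcestph.model import FeatureTable
        fit, X, _ = self._trained()
        n_vox = 5
        table = FeatureTable(X=X[:n_vox], voxel_index=np.array([0, 3, 7, 10, 17]),
                             grid_shape=zvol_shape)
        pm = predict(fit.model, fit.stats, table)
        assert pm.mask.sum() == n_vox
        assert np.isnan(pm.ph_mean.reshape(-1)[1])
        ph_rows, _ = predict_rows(fit.model, fit.stats, table.X)
        assert pm.ph_mean.reshape(-1)[3] == pytest.approx(ph_rows[1])

    def test_voxelwise_permutation_equivariance(self):
        fit, X, _ = self._trained()
        perm = np.random.default_rng(1).permutation(X.shape[0])
        ph, sig = predict_rows(fit.model, fit.stats, X)
        ph_p, sig_p = predict_rows(fit.model, fit.stats, X[perm])
        assert np.allclose(ph_p, ph[perm], atol=1e-12)
        assert np.allclose(sig_p, sig[perm], atol=1e-12)

    def test_feature_dim_mismatch_rejected(self):
        from deepcestph.model import FeatureTable
        fit, X, _ = self._trained()
        table = FeatureTable(X=X[:, :5], voxel_index=np.arange(X.shape[0]),
                             grid_shape=(600, 1, 1))
        with pytest.raises(ValueError):
            predict(fit.model, fit.stats, table)

    def test_checkpoint_roundtrip(self, tmp_path):
        fit, X, _ = self._trained()
        p = tmp_path / "ckpt.json"
        save_checkpoint(p, fit.model, fit.stats, fit.config, "abc")
        model, stats, cfg, h = load_checkpoint(p)
        assert h == "abc"
        ph0, _ = predict_rows(fit.model, fit.stats, X)
        ph1, _ = predict_rows(model, stats, X)
        assert np.allclose(ph0, ph1, atol=1e-12)


class TestT1Attack:
    def _fit_and_table(self):
        rng = np.random.default_rng(6)
        shape = (4, 4, 2)
        n = np.prod(shape)
        X = rng.normal(size=(n, 8))
        X[:, -1] = rng.uniform(1.0, 2.0, n)  # qT1 channel
        y = 7.0 + 0.02 * X[:, 0]
        fit = train(X, y, NetConfig(seed=3, epochs=20, batch_size=32))
        from deepcestph.model import FeatureTable
        table = FeatureTable(X=X, voxel_index=np.arange(n), grid_shape=shape)
        return fit, table, shape

    def test_identical_fake_t1_changes_nothing(self):
        fit, table, shape = self._fit_and_table()
        roi = np.zeros(shape, bool)
        roi[0, 0, 0] = True
        original = table.X[0, -1]
        rep = t1_attack(fit.model, fit.stats, table, roi, original)
        assert rep["median_abs_delta_roi"] == 0.0

    def test_outside_roi_exactly_unchanged(self):
        fit, table, shape = self._fit_and_table()
        roi = np.zeros(shape, bool)
        roi[:2] = True
        rep = t1_attack(fit.model, fit.stats, table, roi, 1.8)
        assert rep["max_abs_delta_outside"] == 0.0

    def test_empty_roi_rejected(self):
        fit, table, shape = self._fit_and_table()
        with pytest.raises(ValueError):
            t1_attack(fit.model, fit.stats, table, np.zeros(shape, bool), 1.8)
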