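"""MIMO regressor construction, linear least-squares fit, MLP + LM training."""

import numpy as np
import pytest

from msvdcast import forecasting as fc
from msvdcast.synthetic import generate_linear_mimo_fixture


class TestBuildRegressors:
    def test_unrolled_lags_single_horizon(self):
        reg = fc.build_regressors([1, 2, 3, 4], [0, 0, 0, 0], [1, 2, 3, 4], P=2, tau=1)
        np.testing.assert_array_equal(reg.z, [[2, 1, 0, 0], [3, 2, 0, 0]])
        np.testing.assert_array_equal(reg.targets, [[3], [4]])
        np.testing.assert_array_equal(reg.row_index_map, [2, 3])

    def test_two_horizons(self):
        reg = fc.build_regressors([1, 2, 3, 4], [0, 0, 0, 0], [1, 2, 3, 4], P=2, tau=2)
        np.testing.assert_array_equal(reg.z, [[2, 1, 0, 0]])
        np.testing.assert_array_equal(reg.targets, [[3, 4]])

    def test_row_count_matches_enumeration(self, rng):
        """Row count equals a brute-force enumeration of valid time indices."""
        for _ in range(20):
            N = int(rng.integers(5, 60))
            P = int(rng.integers(1, 4))
            tau = int(rng.integers(1, 4))
            if N < P + tau:
                continue
            x = rng.standard_normal(N)
            reg = fc.build_regressors(x, x, x, P, tau)
            valid_n = [n for n in range(1, N + 1) if n >= P and n + tau <= N]
            assert reg.n_rows == len(valid_n) == N - P - tau + 1
            np.testing.assert_array_equal(reg.row_index_map, valid_n)

    def test_targets_never_reference_beyond_series(self, rng):
        x = np.arange(1.0, 31.0)
        reg = fc.build_regressors(x, x, x, P=5, tau=3)
        assert reg.targets.max() == 30.0
        assert reg.row_index_map[-1] + reg.tau == 30

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="P \\+ tau"):
            fc.build_regressors([1, 2, 3], [1, 2, 3], [1, 2, 3], P=2, tau=2)


class TestSplit:
    def test_70_30_split(self, rng):
        reg, _ = generate_linear_mimo_fixture(100, 2, 1, 0.0, 0)
        train, test = fc.split_rows(reg, fc.SplitSpec(0.70))
        assert train.n_rows == 70 and test.n_rows == 30

    def test_chronological_no_shuffle(self, rng):
        reg, _ = generate_linear_mimo_fixture(10, 2, 1, 0.0, 0)
        train, test = fc.split_rows(reg, fc.SplitSpec(0.70))
        assert train.n_rows == 7 and test.n_rows == 3
        assert train.row_index_map[-1] < test.row_index_map[0]
        np.testing.assert_array_equal(
            np.concatenate([train.z, test.z]), reg.z
        )

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            fc.SplitSpec(1.0)
        with pytest.raises(ValueError):
            fc.SplitSpec(0.0)


class TestMimoAr:
    def test_noiseless_recovery(self):
        reg, beta_true = generate_linear_mimo_fixture(200, 3, 2, 0.0, 7)
        model = fc.fit_mimo_ar(reg)
        assert model.beta.shape == (2, 6)
        np.testing.assert_allclose(model.beta, beta_true, atol=1e-8)
        np.testing.assert_allclose(
            fc.predict_mimo_ar(model, reg.z), reg.targets, atol=1e-8
        )

    def test_zero_targets_give_zero_coefficients(self, rng):
        reg = fc.RegressorSet(
            z=rng.standard_normal((50, 4)), targets=np.zeros((50, 2)),
            row_index_map=np.arange(50), P=2, tau=2,
        )
        np.testing.assert_allclose(fc.fit_mimo_ar(reg).beta, 0.0, atol=1e-12)

    def test_rank_deficient_design_matches_lstsq_residual(self, rng):
        z = rng.standard_normal((60, 3))
        z = np.hstack([z, z[:, :1]])  # duplicated column
        t = rng.standard_normal((60, 2))
        reg = fc.RegressorSet(z=z, targets=t, row_index_map=np.arange(60), P=2, tau=2)
        model = fc.fit_mimo_ar(reg)
        resid = np.sum((fc.predict_mimo_ar(model, z) - t) ** 2)
        ref_resid = sum(
            np.sum((z @ np.linalg.lstsq(z, t[:, h], rcond=None)[0] - t[:, h]) ** 2)
            for h in range(2)
        )
        assert resid == pytest.approx(ref_resid, abs=1e-8)

    def test_noise_consistency_rmse_shrinks_with_rows(self):
        """Coefficient RMSE decreases across 100 -> 400 -> 1600 rows (3-seed median)."""
        rmses = []
        for rows in (100, 400, 1600):
            per_seed = []
            for seed in range(3):
                reg, beta_true = generate_linear_mimo_fixture(rows, 3, 2, 1.0, seed)
                model = fc.fit_mimo_ar(reg)
                per_seed.append(float(np.sqrt(np.mean((model.beta - beta_true) ** 2))))
            rmses.append(np.median(per_seed))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_shape_mismatch_rejected(self):
        reg, _ = generate_linear_mimo_fixture(50, 2, 1, 0.0, 0)
        model = fc.fit_mimo_ar(reg)
        with pytest.raises(ValueError, match="2P = 4"):
            fc.predict_mimo_ar(model, np.ones((3, 5)))

    def test_inputs_not_mutated(self):
        reg, _ = generate_linear_mimo_fixture(50, 2, 1, 0.5, 1)
        z_before = reg.z.copy()
        fc.fit_mimo_ar(reg)
        np.testing.assert_array_equal(reg.z, z_before)


class TestMlp:
    def test_sigmoid_midpoint_and_saturation(self):
        assert fc.sigmoid(np.array([0.0]))[0] == 0.5
        assert fc.sigmoid(np.array([800.0]))[0] == pytest.approx(1.0)
        assert fc.sigmoid(np.array([-800.0]))[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("n_train, q", [(512, 9), (547, 9), (2, 1), (100, 7)])
    def test_hidden_width_rule(self, n_train, q):
        assert fc.hidden_width(n_train) == q

    def test_init_reproducible(self):
        a = fc.init_mlp(3, 100, 2, seed=42)
        b = fc.init_mlp(3, 100, 2, seed=42)
        np.testing.assert_array_equal(a.input_weights, b.input_weights)
        np.testing.assert_array_equal(a.output_weights, b.output_weights)
        assert a.Q == 7

    def test_zero_weights_forward_pass(self):
        model = fc.MlpModel(
            input_weights=np.zeros((4, 3)), output_weights=np.zeros((3, 2)), Q=3
        )
        pred = fc.predict_mlp(model, np.ones((5, 4)))
        np.testing.assert_array_equal(pred, np.zeros((5, 2)))

    def test_forward_pass_matches_loop_oracle(self, rng):
        w = rng.standard_normal((2, 3))
        b = rng.standard_normal((3, 2))
        model = fc.MlpModel(input_weights=w, output_weights=b, Q=3)
        z = rng.standard_normal((4, 2))
        ref = np.empty((4, 2))
        for n in range(4):
            y = [1.0 / (1.0 + np.exp(-sum(w[i, j] * z[n, i] for i in range(2))))
                 for j in range(3)]
            for h in range(2):
                ref[n, h] = sum(b[j, h] * y[j] for j in range(3))
        np.testing.assert_allclose(fc.predict_mlp(model, z), ref, atol=1e-12)

    def test_hidden_unit_permutation_invariance(self, rng):
        w = rng.standard_normal((4, 5))
        b = rng.standard_normal((5, 3))
        z = rng.standard_normal((6, 4))
        perm = rng.permutation(5)
        a = fc.predict_mlp(fc.MlpModel(input_weights=w, output_weights=b, Q=5), z)
        bperm = fc.predict_mlp(
            fc.MlpModel(input_weights=w[:, perm], output_weights=b[perm], Q=5), z
        )
        np.testing.assert_allclose(a, bperm, atol=1e-12)

    def test_lm_fits_noiseless_linear_map(self):
        reg, _ = generate_linear_mimo_fixture(80, 2, 2, 0.0, 11)
        small = fc.RegressorSet(
            z=reg.z, targets=reg.z @ (0.2 * np.ones((2, 4))).T,
            row_index_map=reg.row_index_map, P=2, tau=2,
        )
        proto = fc.init_mlp(2, small.n_rows, 2, seed=3, Q=6)
        trained, report = fc.train_mlp_lm(proto, small, epochs=500, runs=10, seed=3)
        assert report.final_mse < 1e-4
        assert min(float(c[-1]) for c in report.run_errors) == report.final_mse

    def test_lm_accepted_error_curves_non_increasing(self):
        reg, _ = generate_linear_mimo_fixture(60, 2, 2, 0.3, 5)
        proto = fc.init_mlp(2, reg.n_rows, 2, seed=1, Q=4)
        _, report = fc.train_mlp_lm(proto, reg, epochs=50, runs=3, seed=1)
        for curve in report.run_errors:
            assert np.all(np.diff(curve) <= 1e-12)

    def test_training_reproducible(self):
        reg, _ = generate_linear_mimo_fixture(60, 2, 1, 0.2, 9)
        proto = fc.init_mlp(2, reg.n_rows, 1, seed=4, Q=4)
        m1, r1 = fc.train_mlp_lm(proto, reg, epochs=20, runs=2, seed=4)
        m2, r2 = fc.train_mlp_lm(proto, reg, epochs=20, runs=2, seed=4)
        np.testing.assert_array_equal(m1.input_weights, m2.input_weights)
        assert r1.final_mse == r2.final_mse

    def test_standardization_travels_with_model(self):
        reg, _ = generate_linear_mimo_fixture(60, 2, 1, 0.0, 2)
        shifted = fc.RegressorSet(
            z=reg.z * 100 + 5000, targets=reg.targets,
            row_index_map=reg.row_index_map, P=2, tau=1,
        )
        proto = fc.init_mlp(2, shifted.n_rows, 1, seed=0, Q=4)
        trained, _ = fc.train_mlp_lm(proto, shifted, epochs=30, runs=2, seed=0)
        in_sample = fc.predict_mlp(trained, shifted.z)
        assert np.all(np.isfinite(in_sample))
        assert trained.input_mean is not None
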