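import numpy as np
import pytest

import rewnpls as rw
from conftest import nipals_pls2, run_stream, standardized
from rewnpls.rew_npls import extract_factors
from rewnpls.tensor_ops import matricize_obs


def fit_once(x, y, x_shape, y_shape, f_max, lam=1.0, **kw):
    state, stack = rw.init_state(x_shape, y_shape, lam=lam, f_max=f_max)
    return rw.update(state, stack, x, y, **kw)


class TestInitState:
    def test_accumulator_shapes(self):
        state, stack = rw.init_state((15, 10, 64), (3, 3), f_max=2)
        assert state.cxx_raw.shape == (9600, 9600)
        assert state.cxy_raw.shape == (9600, 9)
        assert stack.is_empty

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            rw.init_state((2,), (1,), f_max=0)
        with pytest.raises(ValueError):
            rw.init_state((2,), (1,), lam=1.5)
        with pytest.raises(ValueError):
            rw.init_state((0,), (1,))

    def test_deterministic(self):
        s1, _ = rw.init_state((3, 2), (2,), lam=0.9, f_max=4)
        s2, _ = rw.init_state((3, 2), (2,), lam=0.9, f_max=4)
        np.testing.assert_array_equal(s1.cxx_raw, s2.cxx_raw)
        assert s1.x_moments.n_eff == s2.x_moments.n_eff == 0.0


class TestUpdate:
    def test_batch_split_invariance_at_lam_one(self, rng):
        x = rng.standard_normal((120, 3, 4))
        y = rng.standard_normal((120, 2))
        state_a, stack_a = fit_once(x, y, (3, 4), (2,), 4, als_tol=1e-13, als_max_iter=500)
        state_b, stack_b = rw.init_state((3, 4), (2,), lam=1.0, f_max=4)
        for lo, hi in [(0, 60), (60, 120)]:
            state_b, stack_b = rw.update(
                state_b, stack_b, x[lo:hi], y[lo:hi], als_tol=1e-13, als_max_iter=500
            )
        np.testing.assert_allclose(state_a.cxy_raw, state_b.cxy_raw, rtol=1e-12)
        np.testing.assert_allclose(state_a.cxx_raw, state_b.cxx_raw, rtol=1e-12)
        for f in range(1, 5):
            a, b = stack_a.coef_matrix(f), stack_b.coef_matrix(f)
            assert np.linalg.norm(a - b) / np.linalg.norm(a) < 1e-8

    def test_lam_zero_total_forgetting(self, rng):
        x = rng.standard_normal((80, 4))
        y = rng.standard_normal((80, 2))
        state_a, stack_a = rw.init_state((4,), (2,), lam=0.0, f_max=2)
        state_a, stack_a = rw.update(state_a, stack_a, x[:40], y[:40])
        state_a, stack_a = rw.update(state_a, stack_a, x[40:], y[40:])
        state_b, stack_b = fit_once(x[40:], y[40:], (4,), (2,), 2, lam=0.0)
        np.testing.assert_allclose(state_a.cxy_raw, state_b.cxy_raw, rtol=1e-12)
        np.testing.assert_allclose(
            stack_a.coef_matrix(2), stack_b.coef_matrix(2), atol=1e-10
        )

    def test_noiseless_residual_decreases_to_ols_exact_fit(self):
        # noiseless linear data: in-sample residual falls monotonically
        # with the factor count and vanishes at the full budget f = I,
        # where the PLS solution coincides with ordinary least squares
        spec = rw.StreamSpec(
            x_shape=(4, 5), y_shape=(3,), rank=2, snr=None,
            batch_size=100, n_batches=3, seed=11,
        )
        truth = rw.make_truth(spec)
        batches = list(rw.gen_batches(spec, truth))
        x = np.concatenate([b.x for b in batches])
        y = np.concatenate([b.y for b in batches])
        _, stack = fit_once(x, y, (4, 5), (3,), 20, als_tol=1e-13, als_max_iter=2000)
        resid = [
            np.linalg.norm(rw.predict(stack, x, f) - y) / np.linalg.norm(y)
            for f in range(1, 21)
        ]
        assert np.all(np.diff(resid) < 1e-12)
        assert resid[-1] < 1e-10

    def test_centered_covariance_identity(self, rng):
        # derived C_XX equals the contraction of the pooled standardized
        # data: exponentially weighted recentring via S/SS/N_eff is exact
        x = rng.standard_normal((50, 3, 2))
        y = rng.standard_normal((50, 2))
        state, stack = rw.init_state((3, 2), (2,), lam=1.0, f_max=2)
        for lo, hi in [(0, 20), (20, 50)]:
            state, stack = rw.update(state, stack, x[lo:hi], y[lo:hi])
        cxx, cxy = state.centered_covariances()
        xs, ys = standardized(x), standardized(y)
        np.testing.assert_allclose(cxx, xs.T @ xs, atol=1e-10)
        np.testing.assert_allclose(cxy, xs.T @ ys, atol=1e-10)

    def test_psd_preserved_after_updates(self, rng):
        state, stack = rw.init_state((3, 2), (2,), lam=0.7, f_max=2)
        for _ in range(6):
            x = rng.standard_normal((10, 3, 2))
            y = rng.standard_normal((10, 2))
            state, stack = rw.update(state, stack, x, y)
            cxx, _ = state.centered_covariances()
            eigs = np.linalg.eigvalsh(cxx)
            assert eigs.min() >= -1e-10 * np.trace(cxx)

    def test_rejects_non_finite_and_mismatched(self, rng):
        state, stack = rw.init_state((2,), (1,), f_max=2)
        with pytest.raises(ValueError, match="non-finite"):
            rw.update(state, stack, np.array([[np.inf, 1.0]]), np.array([[1.0]]))
        with pytest.raises(ValueError, match="shape"):
            rw.update(state, stack, np.ones((3, 5)), np.ones((3, 1)))

    def test_empty_batch_decays_accumulators(self, rng):
        x = rng.standard_normal((20, 2))
        y = rng.standard_normal((20, 1))
        state, stack = fit_once(x, y, (2,), (1,), 2, lam=0.5)
        before = state.cxx_raw.copy()
        state, stack = rw.update(state, stack, np.zeros((0, 2)), np.zeros((0, 1)))
        np.testing.assert_allclose(state.cxx_raw, 0.5 * before, rtol=1e-14)


class TestExtractFactors:
    def test_reduces_to_nipals_pls2_for_vector_inputs(self, rng):
        x = rng.standard_normal((150, 12))
        y = rng.standard_normal((150, 3))
        _, stack = fit_once(x, y, (12,), (3,), 5, als_tol=1e-14, als_max_iter=2000)
        bs = nipals_pls2(standardized(x), standardized(y), 5)
        for f in range(1, 6):
            rel = np.linalg.norm(stack.coef_matrix(f) - bs[f - 1]) / np.linalg.norm(
                bs[f - 1]
            )
            assert rel < 1e-6

    def test_zero_cross_covariance_truncates(self, rng):
        cxx = np.eye(6)
        cxy = np.zeros((6, 2))
        factors, b_mats = extract_factors(cxx, cxy, (3, 2), (2,), f_max=4)
        assert len(factors) == 0
        assert len(b_mats) == 4
        for b in b_mats:
            np.testing.assert_array_equal(b, np.zeros((6, 2)))

    def test_deflation_annihilates_weight_direction(self, rng):
        x = rng.standard_normal((60, 3, 2))
        y = rng.standard_normal((60, 2))
        xs, ys = standardized(x), standardized(y)
        cxx, cxy = xs.T @ xs, xs.T @ ys
        deflated = cxy.copy()
        factors, _ = extract_factors(cxx, cxy, (3, 2), (2,), f_max=3)
        for fac in factors:
            deflated = deflated - fac.tt * np.outer(fac.p, fac.q)
            assert np.abs(fac.r @ deflated).max() < 1e-9

    def test_rank_one_coefficient_increments(self, rng):
        x = rng.standard_normal((60, 4))
        y = rng.standard_normal((60, 2))
        _, stack = fit_once(x, y, (4,), (2,), 3)
        prev = np.zeros((4, 2))
        for f in range(1, stack.n_valid + 1):
            diff = stack.coef_matrix(f) - prev
            assert np.linalg.matrix_rank(diff, tol=1e-10) == 1
            prev = stack.coef_matrix(f)

    def test_warm_start_reaches_same_fixed_point(self, rng):
        x = rng.standard_normal((100, 3, 2))
        y = rng.standard_normal((100, 2))
        xs, ys = standardized(x), standardized(y)
        cxx, cxy = xs.T @ xs, xs.T @ ys
        cold, b_cold = extract_factors(cxx, cxy, (3, 2), (2,), 3, als_tol=1e-14, als_max_iter=2000)
        warm, b_warm = extract_factors(
            cxx, cxy, (3, 2), (2,), 3, warm_start=cold, als_tol=1e-14,
            als_max_iter=2000, init_policy="warm",
        )
        np.testing.assert_allclose(b_warm[-1], b_cold[-1], atol=1e-8)


class TestPredict:
    def test_zero_model_predicts_mean(self, rng):
        # constant Y: centered C_XY vanishes, so the model is the intercept
        x = rng.standard_normal((30, 4))
        y = np.tile(rng.standard_normal(2), (30, 1))
        _, stack = fit_once(x, y, (4,), (2,), 2)
        pred = rw.predict(stack, rng.standard_normal((5, 4)), 1)
        np.testing.assert_allclose(pred, np.tile(y[0], (5, 1)), atol=1e-8)

    def test_two_path_equivalence(self, rng):
        x = rng.standard_normal((70, 3, 2, 2))
        y = rng.standard_normal((70, 2, 2))
        _, stack = fit_once(x, y, (3, 2, 2), (2, 2), 3)
        x_new = rng.standard_normal((9, 3, 2, 2))
        direct = rw.predict(stack, x_new, 2)
        xs = (matricize_obs(x_new) - stack.mu_x) / stack.sigma_x
        via_std = xs @ stack.coef_matrix(2) * stack.sigma_y + stack.mu_y
        assert np.abs(matricize_obs(direct) - via_std).max() < 1e-10

    def test_single_epoch_noiseless_ground_truth(self):
        spec = rw.StreamSpec(
            x_shape=(3, 4), y_shape=(2,), rank=2, snr=None,
            batch_size=200, n_batches=2, seed=3,
        )
        truth, _, stack, _ = run_stream(spec, f_max=12, als_tol=1e-13, als_max_iter=2000)
        probe = rw.StreamSpec(
            x_shape=(3, 4), y_shape=(2,), rank=2, snr=None,
            batch_size=1, n_batches=1, seed=99,
        )
        batch = next(iter(rw.gen_batches(probe, rw.make_truth(probe))))
        x1 = batch.x
        y_true = matricize_obs(x1) @ truth.b_mat()
        pred = rw.predict(stack, x1, 12)
        assert np.linalg.norm(pred - y_true) / np.linalg.norm(y_true) < 1e-5

    def test_factor_beyond_truncation_warns_and_aliases(self, rng):
        x = rng.standard_normal((40, 3))
        b = rng.standard_normal((3, 1))
        y = x @ b  # single output: one factor direction, then truncation
        _, stack = fit_once(x, y, (3,), (1,), 5, als_tol=1e-13, als_max_iter=500)
        assert stack.n_valid < 5
        x_new = rng.standard_normal((4, 3))
        with pytest.warns(RuntimeWarning, match="truncated"):
            late = rw.predict(stack, x_new, 5)
        valid = rw.predict(stack, x_new, stack.n_valid)
        np.testing.assert_array_equal(late, valid)

    def test_forgetting_tracks_switch(self):
        # coefficient switch mid-stream: lam<1 must beat lam=1 on the final batch
        spec = rw.StreamSpec(
            x_shape=(3, 4), y_shape=(2,), rank=2, snr=20.0,
            batch_size=60, n_batches=30, drift=rw.SwitchDrift(at_batch=15), seed=7,
        )
        errs = {}
        for lam in (0.9, 1.0):
            final = {}

            def record(batch, rv, stack, final=final):
                if batch.index == spec.n_batches - 1 and not stack.is_empty:
                    pred = rw.predict(stack, batch.x, rv.f_star)
                    final["mse"] = float(np.mean((pred - batch.y) ** 2))

            run_stream(spec, lam=lam, gamma=0.8, f_max=6, record=record)
            errs[lam] = final["mse"]
        assert errs[0.9] < errs[1.0]
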