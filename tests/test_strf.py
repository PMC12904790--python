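import numpy as np
import pytest

from gluim import strf as gs
from gluim import synthgen as sg


@pytest.fixture(scope="module")
def small_session():
    """4x4 grid, 300 s of 5 Hz sparse noise, 10 Hz responses, known ON/OFF RF."""
    rng = np.random.default_rng(5)
    stim = sg.simulate_sparse_noise_stimulus(1500, (4, 4), seed=rng)
    gy, gx, rate, n_lags = 4, 4, 10.0, 8
    rr, cc = np.mgrid[:gy, :gx]
    blob = np.exp(-(((rr - 1.5) ** 2 + (cc - 2.2) ** 2)) / (2 * 0.8**2))
    lagprof = np.zeros(n_lags)
    lagprof[1:6] = np.hanning(5)
    rf_on = blob[None, :, :, None] * lagprof[None, None, None, :]
    rf_off = 0.5 * rf_on
    clean, design = sg.simulate_sparse_noise_session(stim, rf_on, rf_off, 0.0, rate)
    return {
        "stim": stim,
        "design": design,
        "clean": clean[0],
        "rf_on": rf_on[0],
        "rf_off": rf_off[0],
        "center": (1.5, 2.2),
        "rate": rate,
    }


class TestBuildDesign:
    def test_column_count(self):
        stim = sg.simulate_sparse_noise_stimulus(100, (3, 5), seed=0)
        d = gs.build_design(stim, 10.0, max_lag=0.5)
        n_lags = int(round(0.5 * 10.0)) + 1
        assert d.X.shape[1] == 2 * 3 * 5 * n_lags
        assert d.n_lags == n_lags

    def test_all_gray_zero_matrix(self):
        stim = sg.SparseNoiseStimulus(np.zeros((50, 4, 4), np.int8), 5.0, 0.0)
        d = gs.build_design(stim, 10.0, max_lag=0.4)
        assert not d.X.any()

    def test_single_flash_diagonal_streak(self):
        frames = np.zeros((20, 2, 2), np.int8)
        frames[4, 0, 1] = 1  # single white flash
        stim = sg.SparseNoiseStimulus(frames, 5.0, 0.0)
        d = gs.build_design(stim, 5.0, max_lag=0.6)  # 1:1 sampling, 4 lags
        nl = d.n_lags
        on = d.X[:, : 4 * nl].reshape(20, 4, nl)
        off = d.X[:, 4 * nl :]
        assert not off.any()
        cell = 0 * 2 + 1  # pixel (0, 1) flattened
        for lag in range(nl):
            assert on[4 + lag, cell, lag] == 1.0
        on[4 : 4 + nl, cell, range(nl)] = 0.0
        assert not on.any()

    def test_causality_zero_padding(self):
        frames = np.ones((10, 1, 1), np.int8)
        stim = sg.SparseNoiseStimulus(frames, 5.0, 1.0)
        d = gs.build_design(stim, 5.0, max_lag=0.4)
        assert d.X[0, 1] == 0.0  # lag-1 column has no history at t=0
        assert d.X[1, 1] == 1.0

    def test_invalid_max_lag(self):
        stim = sg.simulate_sparse_noise_stimulus(10, (2, 2), seed=0)
        with pytest.raises(ValueError):
            gs.build_design(stim, 10.0, max_lag=0.0)


class TestFitStrf:
    def test_noiseless_recovery_high_correlation(self, small_session):
        s = small_session
        w = gs.fit_strf(s["design"], s["clean"], lam=1e-3)
        on, off = s["design"].unpack(w)
        truth = np.concatenate([s["rf_on"].ravel(), s["rf_off"].ravel()])
        est = np.concatenate([on.ravel(), off.ravel()])
        assert np.corrcoef(truth, est)[0, 1] > 0.99

    def test_large_lambda_spatially_constant(self, small_session):
        s = small_session
        w = gs.fit_strf(s["design"], s["clean"], lam=1e9)
        on, _ = s["design"].unpack(w)
        per_lag_spatial_sd = on.reshape(-1, s["design"].n_lags).std(axis=0)
        per_lag_mean = np.abs(on.reshape(-1, s["design"].n_lags).mean(axis=0))
        assert (per_lag_spatial_sd <= 0.05 * per_lag_mean.max() + 1e-9).all()

    def test_negative_lambda_rejected(self, small_session):
        with pytest.raises(ValueError):
            gs.fit_strf(small_session["design"], small_session["clean"], lam=-1.0)


class TestExplainedVariance:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert gs.explained_variance(y, y) == 1.0

    def test_mean_prediction_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert gs.explained_variance(y, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_hand_worked_example(self):
        # y=[1,2,3], yhat=[1,1,1]: EV = 1 - (0+1+4)/2 = -1.5
        assert gs.explained_variance([1.0, 2.0, 3.0], [1.0, 1.0, 1.0]) == pytest.approx(-1.5)

    def test_zero_variance_undefined(self):
        assert np.isnan(gs.explained_variance([2.0, 2.0], [1.0, 2.0]))


class TestCrossvalLambda:
    def test_noiseless_picks_small_lambda_ev_near_one(self, small_session):
        s = small_session
        grid = gs.default_lambda_grid(s["design"], n_per_decade=1, n_decades=6)
        lam, w, ev, _ = gs.crossval_lambda(s["design"], s["clean"], lambdas=grid)
        assert lam == grid[0]
        assert ev.max() > 0.999

    def test_noise_response_returns_lambda_low_ev(self, small_session, rng):
        s = small_session
        y = rng.normal(size=s["clean"].size)
        grid = gs.default_lambda_grid(s["design"], n_per_decade=1, n_decades=6)
        lam, w, ev, _ = gs.crossval_lambda(s["design"], y, lambdas=grid)
        assert lam in grid
        assert ev.max() < 0.05

    def test_permuted_response_nonpositive_cv_ev(self, small_session):
        s = small_session
        y = np.random.default_rng(0).permutation(s["clean"])
        grid = gs.default_lambda_grid(s["design"], n_per_decade=1, n_decades=4)
        _, _, ev, _ = gs.crossval_lambda(s["design"], y, lambdas=grid)
        assert ev.max() <= 0.02


class TestCircularShiftTest:
    def test_strong_rf_floor_p(self, small_session):
        s = small_session
        p = gs.circular_shift_test(s["design"], s["clean"], 1e-3, n_shifts=200, seed=0)
        assert p == 1.0 / 200

    def test_seed_reproducibility(self, small_session):
        s = small_session
        y = np.random.default_rng(1).normal(size=s["clean"].size)
        p1 = gs.circular_shift_test(s["design"], y, 1.0, n_shifts=200, seed=7)
        p2 = gs.circular_shift_test(s["design"], y, 1.0, n_shifts=200, seed=7)
        assert p1 == p2

    def test_too_few_shifts_rejected(self, small_session):
        with pytest.raises(ValueError):
            gs.circular_shift_test(small_session["design"], small_session["clean"], 1.0, n_shifts=1)


class TestClassifyResponsive:
    @pytest.mark.parametrize(
        "ev,p,expected",
        [(0.15, 0.001, True), (0.15, 0.02, False), (0.09, 0.0001, False), (0.1, 0.001, False)],
    )
    def test_thresholds(self, ev, p, expected):
        assert gs.classify_responsive(ev, p) is expected


class TestSpatialRf:
    def test_center_recovery(self, small_session):
        s = small_session
        w = gs.fit_strf(s["design"], s["clean"], lam=1e-3)
        sl, best_lag, g = gs.spatial_rf(s["design"], w)
        assert g.converged
        assert g.center[0] == pytest.approx(s["center"][0], abs=0.3)
        assert g.center[1] == pytest.approx(s["center"][1], abs=0.3)

    def test_pure_on_rf_combined_is_half_on(self, small_session):
        s = small_session
        resp, design = sg.simulate_sparse_noise_session(
            s["stim"], s["rf_on"][None], np.zeros_like(s["rf_on"])[None], 0.0, s["rate"]
        )
        w = gs.fit_strf(design, resp[0], lam=1e-3)
        on, off = design.unpack(w)
        sl, _, _ = gs.spatial_rf(design, w)
        best = int(np.argmax(np.abs(on - off).reshape(-1, design.n_lags).max(axis=0)))
        np.testing.assert_allclose(sl, (on[:, :, best] - off[:, :, best]) / 2.0)

    def test_symmetric_truth_equal_sigmas(self):
        rr, cc = np.mgrid[:9, :9]
        img = np.exp(-(((rr - 4) ** 2 + (cc - 4) ** 2)) / (2 * 1.5**2))
        g = gs.fit_gaussian_2d(img)
        assert g.sigmas[0] == pytest.approx(g.sigmas[1], rel=0.05)
        assert g.center[0] == pytest.approx(4.0, abs=0.1)


class TestEndToEnd:
    def test_recovery_and_shuffle_control(self, small_session):
        s = small_session
        rng = np.random.default_rng(2)
        noise_sd = s["clean"].std() / 5.0  # response SNR 5
        y = s["clean"] + rng.normal(0, noise_sd, s["clean"].size)
        grid = gs.default_lambda_grid(s["design"], n_per_decade=2, n_decades=6)
        r = gs.map_strf(s["design"], y, lambdas=grid, n_shifts=400, seed=0)
        assert r.ev_cv > 0.3
        assert r.responsive
        assert abs(r.spatial_gaussian.center[0] - s["center"][0]) < 1.0
        assert abs(r.spatial_gaussian.center[1] - s["center"][1]) < 1.0
        # shuffled responses: not responsive
        ysh = rng.permutation(y)
        r2 = gs.map_strf(s["design"], ysh, lambdas=grid, n_shifts=400, seed=0)
        assert not r2.responsive

    def test_full_ev_optimism(self, small_session):
        # EV of the full fit >= cross-validated EV in expectation
        s = small_session
        rng = np.random.default_rng(3)
        grid = gs.default_lambda_grid(s["design"], n_per_decade=1, n_decades=4)
        diffs = []
        for i in range(10):
            y = s["clean"] + rng.normal(0, s["clean"].std(), s["clean"].size)
            lam, w, ev, _ = gs.crossval_lambda(s["design"], y, lambdas=grid)
            ev_full = gs.explained_variance(y, s["design"].X @ w)
            diffs.append(ev_full - np.nanmax(ev))
        assert np.mean(diffs) > 0
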