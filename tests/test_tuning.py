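import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gluim import kinetics as gk
from gluim import synthgen as sg
from gluim import tuning as gt

DIRS = np.arange(8) * 45.0


def make_log(n_trials_per_dir, trial_len=3.0, gray=1.0, seed=0):
    rng = np.random.default_rng(seed)
    order = np.repeat(DIRS, n_trials_per_dir)
    rng.shuffle(order)
    onsets = gray + np.arange(order.size) * trial_len
    return pd.DataFrame({"onset_s": onsets, "direction_deg": order})


class TestTimeResolvedTuning:
    def test_identical_trials_mean_equals_trial(self):
        fr = 10.0
        log = make_log(3)
        T = int((log["onset_s"].iloc[-1] + 3) * fr)
        x = np.zeros(T)
        for onset in log["onset_s"]:
            k = int(onset * fr)
            x[k : k + 20] = 1.0
        tr = gt.time_resolved_tuning(x, fr, log)
        assert tr.traces.shape == (8, int(2.5 * fr))
        np.testing.assert_allclose(tr.traces[:, tr.n_pre :], 1.0)

    def test_trial_order_permutation_invariance(self, rng):
        fr = 10.0
        log = make_log(4, seed=1)
        T = int((log["onset_s"].iloc[-1] + 3) * fr)
        x = rng.normal(size=T)
        t1 = gt.time_resolved_tuning(x, fr, log)
        perm = log.sample(frac=1.0, random_state=3).reset_index(drop=True)
        t2 = gt.time_resolved_tuning(x, fr, perm)
        np.testing.assert_allclose(t1.traces, t2.traces)

    def test_missing_direction_absent(self):
        fr = 10.0
        log = make_log(2)
        log = log[log["direction_deg"] != 90.0]
        T = int((log["onset_s"].max() + 3) * fr)
        tr = gt.time_resolved_tuning(np.zeros(T), fr, log)
        assert 90.0 not in tr.directions
        assert tr.traces.shape[0] == 7

    def test_tuned_site_max_at_preferred(self, tuned_session):
        movie, log = tuned_session
        fps = movie.ground_truth["footprints"]
        tun = movie.ground_truth["tuning"]
        frames = np.asarray(movie.frames, float)
        w = fps[0] / fps[0].sum()
        trace = frames.reshape(frames.shape[0], -1) @ w.ravel()
        dff = gk.compute_dff(gk.Trace(trace, movie.frame_rate), window_frames=401)
        tr = gt.time_resolved_tuning(dff.values, movie.frame_rate, log)
        eight = gt.eight_point_tuning(tr)
        best = tr.directions[int(np.argmax(eight))]
        assert best % 180 == tun.preferred_deg[0] % 180


class TestEightPointTuning:
    def test_flat_trace_zeros(self):
        fr = 10.0
        log = make_log(2)
        T = int((log["onset_s"].iloc[-1] + 3) * fr)
        tr = gt.time_resolved_tuning(np.full(T, 3.3), fr, log)
        np.testing.assert_allclose(gt.eight_point_tuning(tr), 0.0, atol=1e-12)

    def test_offset_invariance(self, rng):
        fr = 10.0
        log = make_log(3, seed=2)
        T = int((log["onset_s"].iloc[-1] + 3) * fr)
        x = rng.normal(size=T)
        e1 = gt.eight_point_tuning(gt.time_resolved_tuning(x, fr, log))
        e2 = gt.eight_point_tuning(gt.time_resolved_tuning(x + 7.0, fr, log))
        np.testing.assert_allclose(e1, e2, atol=1e-9)

    def test_rate_ratio_recovered(self):
        # deterministic rate construction: response ratio ~ rate ratio
        fr = 20.0
        log = make_log(6, seed=3)
        T = int((log["onset_s"].iloc[-1] + 3) * fr)
        x = np.zeros(T)
        rate = {d: (2.0 if d in (0.0, 180.0) else 0.5) for d in DIRS}
        for onset, d in zip(log["onset_s"], log["direction_deg"]):
            k = int(onset * fr)
            x[k : k + int(2 * fr)] = rate[d]
        eight = gt.eight_point_tuning(gt.time_resolved_tuning(x, fr, log))
        assert eight[0] / eight[2] == pytest.approx(4.0, rel=0.05)


class TestOrientationStats:
    def test_single_orientation_pair(self):
        r = np.zeros(8)
        r[0] = r[4] = 1.5  # 0 and 180 deg: same orientation
        s = gt.orientation_stats(r, DIRS)
        assert s.osi == pytest.approx(1.0)
        assert s.preferred_deg == pytest.approx(0.0, abs=1e-9)

    def test_uniform_zero_osi(self):
        s = gt.orientation_stats(np.ones(8), DIRS)
        assert s.osi == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        r = np.zeros(8)
        r[0], r[2] = 2.0, 1.0  # 0 deg: 2, 90 deg: 1
        s = gt.orientation_stats(r, DIRS)
        assert s.osi == pytest.approx(1.0 / 3.0)
        assert s.osi_raw == pytest.approx(1.0)
        assert s.preferred_deg == pytest.approx(0.0, abs=1e-9)
        assert s.tuning_magnitude == pytest.approx(np.sqrt(5.0))
        assert s.response_amplitude == pytest.approx(3.0 / 8.0)

    def test_all_zero_undefined(self):
        s = gt.orientation_stats(np.zeros(8), DIRS)
        assert np.isnan(s.preferred_deg)
        assert s.osi == 0.0

    @settings(max_examples=50, deadline=None)
    @given(arrays(float, 8, elements=st.floats(0.0, 100.0)))
    def test_osi_in_unit_interval(self, r):
        s = gt.orientation_stats(r, DIRS)
        assert 0.0 <= s.osi <= 1.0 + 1e-12

    @settings(max_examples=50, deadline=None)
    @given(arrays(float, 8, elements=st.floats(0.01, 100.0)))
    def test_rotation_by_45_deg(self, r):
        s1 = gt.orientation_stats(r, DIRS)
        s2 = gt.orientation_stats(r, DIRS + 45.0)
        assert s2.osi == pytest.approx(s1.osi, rel=1e-9, abs=1e-12)
        if s1.osi > 1e-6:
            shifted = (s1.preferred_deg + 45.0) % 180.0
            diff = abs(s2.preferred_deg - shifted)
            assert min(diff, 180.0 - diff) < 1e-6


class TestTuningMap:
    def test_untuned_pixels_gray(self):
        rgb = gt.tuning_map(np.full((4, 4), 30.0), np.zeros((4, 4)), np.ones((4, 4)))
        # zero saturation: R == G == B
        assert np.allclose(rgb[..., 0], rgb[..., 1])
        assert np.allclose(rgb[..., 1], rgb[..., 2])

    def test_orthogonal_orientations_opposite_hues(self):
        pref = np.array([[0.0, 90.0]])
        rgb = gt.tuning_map(pref, np.ones((1, 2)), np.ones((1, 2)))
        # hue 0 -> red max; hue 0.5 -> cyan (red min)
        assert rgb[0, 0, 0] > rgb[0, 0, 2]
        assert rgb[0, 1, 0] < rgb[0, 1, 2]

    def test_value_normalized_to_one(self):
        amp = np.array([[1.0, 5.0], [2.0, 0.5]])
        rgb = gt.tuning_map(np.zeros((2, 2)), np.zeros((2, 2)), amp)
        assert rgb.max() == pytest.approx(1.0)


class TestCrossvalSpread:
    def _shared_source_setup(self, seed, shared_noise_sd=1.0, indep_sd=0.5):
        rng = np.random.default_rng(seed)
        fr, L = 20.0, int(2.5 * 20)
        sig = rng.normal(0, 1.0, (8, L))
        log = make_log(12, seed=seed)
        T = int((log["onset_s"].iloc[-1] + 3) * fr)
        v = np.zeros((2, T))
        for onset, d in zip(log["onset_s"], log["direction_deg"]):
            k = int(round(onset * fr))
            di = int(d // 45)
            shared = sig[di] + rng.normal(0, shared_noise_sd, L)
            sl = slice(k - int(0.5 * fr), k + int(2 * fr))
            v[0, sl] += shared + rng.normal(0, indep_sd, L)
            v[1, sl] += shared + rng.normal(0, indep_sd, L)
        truth = np.var(sig.ravel(), ddof=1)
        return v, log, fr, truth

    def test_unbiased_for_signal_covariance(self):
        covs, truths, naives = [], [], []
        for seed in range(60):
            v, log, fr, truth = self._shared_source_setup(seed)
            cov, _ = gt.cv_pair_covariance(v, fr, log, np.array([[0, 1]]), n_splits=20, seed=seed)
            covs.append(cov[0])
            truths.append(truth)
            tr = gt.time_resolved_tuning(v, fr, log)
            naives.append(np.cov(tr.traces[:, 0, :].ravel(), tr.traces[:, 1, :].ravel())[0, 1])
        sem = np.std(covs, ddof=1) / np.sqrt(len(covs))
        assert abs(np.mean(covs) - np.mean(truths)) < 2 * sem + 0.02
        # naive same-trial covariance is biased upward by the shared noise
        assert np.mean(naives) > np.mean(covs) + 2 * sem

    def test_independent_pixels_zero(self, rng):
        fr = 20.0
        log = make_log(8, seed=9)
        T = int((log["onset_s"].iloc[-1] + 3) * fr)
        v = rng.normal(size=(2, T))
        cov, _ = gt.cv_pair_covariance(v, fr, log, np.array([[0, 1]]), n_splits=20, seed=0)
        assert abs(cov[0]) < 0.05

    def test_too_few_trials_rejected(self):
        log = make_log(2)
        with pytest.raises(ValueError):
            gt.cv_pair_covariance(np.zeros((2, 1000)), 10.0, log, np.array([[0, 1]]))

    def test_spread_distance_tracks_footprint_sigma(self):
        # analytic oracle: pixels driven by one source with Gaussian spatial
        # weights exp(-r^2 / 2 sigma^2); pair (center, r) covariance drops to
        # 1/e of maximum at r = sigma * sqrt(2)
        fr, L = 20.0, int(2.5 * 20)
        estimates = []
        for sigma in (1.5, 3.0):
            rng = np.random.default_rng(int(sigma * 10))
            log = make_log(12, seed=int(sigma))
            sig = rng.normal(0, 1.0, (8, L))
            T = int((log["onset_s"].iloc[-1] + 3) * fr)
            radii = np.arange(0, 13)
            weights = np.exp(-(radii**2) / (2 * sigma**2))
            v = np.zeros((radii.size, T))
            for onset, d in zip(log["onset_s"], log["direction_deg"]):
                k = int(round(onset * fr))
                di = int(d // 45)
                sl = slice(k - int(0.5 * fr), k + int(2 * fr))
                v[:, sl] += weights[:, None] * sig[di][None, :]
            v += rng.normal(0, 0.05, v.shape)
            pairs = np.array([[0, j] for j in radii])
            cov, _ = gt.cv_pair_covariance(v, fr, log, pairs, n_splits=10, seed=1)
            curve = gt.spread_curve(radii.astype(float), cov, bin_width=1.0)
            assert curve.d_1e == pytest.approx(sigma * np.sqrt(2), rel=0.25)
            estimates.append(curve.d_1e)
        assert estimates[0] < estimates[1]

    def test_crossval_spread_bootstrap_cis(self):
        recs = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            d = np.repeat(np.arange(10.0), 20)
            vals = np.exp(-d / 3.0) + rng.normal(0, 0.02, d.size)
            recs.append((d, vals))
        curve = gt.crossval_spread(recs, n_boot=200, seed=0)
        assert curve.d_1e is not None and curve.d_1e2 is not None
        assert curve.d_1e <= curve.d_1e2
        lo, hi = curve.ci_d_1e
        assert lo <= curve.d_1e <= hi
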