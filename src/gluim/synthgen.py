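"""Synthetic data generation for indicator-imaging analyses.

Every generator embeds its ground truth (footprints, event trains, kinetic
parameters, tuning curves, receptive fields) so downstream estimators can be
validated by parameter recovery. Movies follow a simple imaging-physics
model: static structural background plus point sources with Gaussian
footprints, each modulated by an indicator transient kernel, with per-pixel
Poisson shot noise and optional slow mono-exponential bleaching.

Conventions: all times are seconds from movie start; frame ``k`` spans
``[k/frame_rate, (k+1)/frame_rate)``; stimulus onsets are snapped to the
nearest frame (sample-and-hold alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import as_rng, check_nonnegative, check_positive

__all__ = [
    "KineticParams",
    "SimConfig",
    "ReleaseTrain",
    "SyntheticMovie",
    "SparseNoiseStimulus",
    "TuningGroundTruth",
    "indicator_kernel",
    "simulate_release_train",
    "gaussian_footprint",
    "render_movie",
    "make_tuning",
    "simulate_tuned_session",
    "simulate_sparse_noise_stimulus",
    "simulate_sparse_noise_session",
    "simulate_photometry",
]

FOOTPRINT_TRUNCATION_SIGMAS = 4.0


@dataclass(frozen=True)
class KineticParams:
    """Rise/decay transient parameters: f(t) = A(1-e^(-t/tau_rise))e^(-t/tau_decay)."""

    amplitude: float  # dF/F units
    tau_rise: float  # s
    tau_decay: float  # s
    t0: float = 0.0  # s, event/AP time

    def __post_init__(self):
        check_nonnegative(self.amplitude, "amplitude")
        check_positive(self.tau_rise, "tau_rise")
        check_positive(self.tau_decay, "tau_decay")

    @property
    def time_to_peak(self) -> float:
        """Closed-form argmax of the kernel relative to t0."""
        return self.tau_rise * np.log1p(self.tau_decay / self.tau_rise)

    @property
    def peak(self) -> float:
        """Kernel value at its argmax (the transient amplitude)."""
        tp = self.time_to_peak
        return self.amplitude * (1 - np.exp(-tp / self.tau_rise)) * np.exp(-tp / self.tau_decay)


@dataclass(frozen=True)
class SimConfig:
    frame_rate: float  # Hz
    duration: float  # s
    image_shape: tuple[int, int] = (64, 64)
    n_sites: int = 5
    footprint_sigma: float = 1.5  # px
    baseline_photon_rate: float = 20.0  # photons/frame/px
    site_brightness: float = 50.0  # photons/frame at footprint peak
    bleach_tau: float | None = None  # s
    rng_seed: int = 0

    def __post_init__(self):
        check_positive(self.frame_rate, "frame_rate")
        check_positive(self.duration, "duration")
        check_nonnegative(self.baseline_photon_rate, "baseline_photon_rate")
        check_nonnegative(self.site_brightness, "site_brightness")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if self.bleach_tau is not None:
            check_positive(self.bleach_tau, "bleach_tau")

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration))


@dataclass
class ReleaseTrain:
    site_id: int
    event_times: np.ndarray  # s, strictly increasing, within [0, duration)

    def __post_init__(self):
        t = np.asarray(self.event_times, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("event_times must be strictly increasing")
        self.event_times = t


@dataclass
class TuningGroundTruth:
    """Direction tuning ground truth for a population of sites."""

    directions: np.ndarray  # degrees, the 8 stimulus directions
    preferred_deg: np.ndarray  # per-site preferred direction (one of directions)
    concentration: np.ndarray  # per-site von-Mises-like concentration (0 = untuned)
    rates: np.ndarray  # n_sites x n_directions mean event rates (events/s)

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=float)
        if np.any(np.mod(d, 45.0) != 0):
            raise ValueError("directions must be multiples of 45 degrees")


@dataclass
class SyntheticMovie:
    frames: np.ndarray  # T x rows x cols, nonnegative integer photon counts
    frame_rate: float
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class SparseNoiseStimulus:
    frames: np.ndarray  # T x gridY x gridX in {-1, 0, +1}
    refresh_rate: float  # Hz
    p_nongray: float


def indicator_kernel(params: KineticParams, frame_rate: float, support: float) -> np.ndarray:
    """Sample the transient kernel A(1-e^(-t/tau_rise))e^(-t/tau_decay) on the frame grid.

    t0 is taken as 0; the kernel is zero for t < 0 and f(0) = 0 exactly.
    ``support`` should be at least ~5 tau_decay for negligible truncation.
    """
    check_positive(frame_rate, "frame_rate")
    check_positive(support, "support")
    t = np.arange(int(round(support * frame_rate))) / frame_rate
    return params.amplitude * (1.0 - np.exp(-t / params.tau_rise)) * np.exp(-t / params.tau_decay)


def simulate_release_train(
    rate: float,
    duration: float,
    locked_times=None,
    p_release: float = 1.0,
    seed=None,
    site_id: int = 0,
) -> ReleaseTrain:
    """Homogeneous-Poisson spontaneous events plus Bernoulli stimulus-locked events.

    Each time in ``locked_times`` produces an event with probability
    ``p_release``; spontaneous events arrive at ``rate`` per second. The
    merged train is sorted and restricted to [0, duration).
    """
    check_nonnegative(rate, "rate")
    check_positive(duration, "duration")
    if not 0.0 <= p_release <= 1.0:
        raise ValueError("p_release must lie in [0, 1]")
    rng = as_rng(seed)
    n_spont = rng.poisson(rate * duration)
    times = rng.uniform(0.0, duration, size=n_spont)
    if locked_times is not None:
        locked = np.asarray(locked_times, dtype=float)
        keep = rng.random(locked.size) < p_release
        times = np.concatenate([times, locked[keep]])
    times = np.sort(times[(times >= 0) & (times < duration)])
    # break exact ties (measure-zero for Poisson, possible with locked times)
    if times.size > 1:
        dup = np.diff(times) <= 0
        while np.any(dup):
            times[1:][dup] = np.nextafter(times[1:][dup], np.inf)
            times = np.sort(times)
            dup = np.diff(times) <= 0
    return ReleaseTrain(site_id=site_id, event_times=times)


def gaussian_footprint(shape: tuple[int, int], center: tuple[float, float], sigma: float) -> np.ndarray:
    """Unit-peak isotropic Gaussian truncated at 4 sigma."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    fp = np.exp(-d2 / (2.0 * sigma**2))
    fp[d2 > (FOOTPRINT_TRUNCATION_SIGMAS * sigma) ** 2] = 0.0
    return fp


def _site_traces(config: SimConfig, trains, kinetics: KineticParams) -> np.ndarray:
    """Per-site ideal dF/F traces: event impulses convolved with the kernel."""
    T = config.n_frames
    support = min(config.duration, 10.0 * kinetics.tau_decay + 5.0 * kinetics.tau_rise)
    kern = indicator_kernel(kinetics, config.frame_rate, support)
    traces = np.zeros((config.n_sites, T))
    for train in trains:
        if train.site_id >= config.n_sites:
            raise ValueError(f"train references site_id {train.site_id} >= n_sites")
        impulses = np.zeros(T)
        idx = np.round(train.event_times * config.frame_rate).astype(int)
        idx = idx[(idx >= 0) & (idx < T)]
        np.add.at(impulses, idx, 1.0)
        traces[train.site_id] = np.convolve(impulses, kern)[:T]
    return traces


def _default_centers(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    margin = FOOTPRINT_TRUNCATION_SIGMAS * config.footprint_sigma
    rows, cols = config.image_shape
    lo = np.array([min(margin, rows / 2 - 1), min(margin, cols / 2 - 1)])
    hi = np.array([rows - lo[0], cols - lo[1]])
    return rng.uniform(lo, hi, size=(config.n_sites, 2))


def render_movie(
    config: SimConfig,
    trains,
    kinetics: KineticParams,
    centers=None,
    noiseless: bool = False,
) -> SyntheticMovie:
    """Render a Poisson photon-count movie with embedded ground truth.

    Pixel expectation at frame t:
        baseline + sum_site footprint * site_brightness * (1 + trace_site(t))
    optionally multiplied by exp(-t/bleach_tau). Each pixel-frame is drawn
    independently Poisson. ``noiseless=True`` returns the expectation itself
    (float frames), which is the reference for recovery tests.
    """
    rng = as_rng(config.rng_seed)
    rows, cols = config.image_shape
    if centers is None:
        centers = _default_centers(config, rng)
    else:
        centers = np.asarray(centers, dtype=float)
    footprints = np.stack(
        [gaussian_footprint((rows, cols), c, config.footprint_sigma) for c in centers]
    ) if config.n_sites else np.zeros((0, rows, cols))
    traces = _site_traces(config, trains, kinetics)

    expect = np.full((config.n_frames, rows, cols), float(config.baseline_photon_rate))
    if config.n_sites:
        expect += config.site_brightness * np.einsum("st,sij->tij", 1.0 + traces, footprints)
    if config.bleach_tau is not None:
        t = np.arange(config.n_frames) / config.frame_rate
        expect *= np.exp(-t / config.bleach_tau)[:, None, None]
    if not np.all(np.isfinite(expect)) or np.any(expect < 0):
        raise FloatingPointError("pixel expectation overflowed or went negative")

    frames = expect if noiseless else rng.poisson(expect).astype(np.int32)
    gt = {
        "footprints": footprints,
        "centers": centers,
        "trains": list(trains),
        "kinetics": kinetics,
        "traces": traces,
        "config": config,
    }
    return SyntheticMovie(frames=frames, frame_rate=config.frame_rate, ground_truth=gt)


def make_tuning(
    n_sites: int,
    kappa,
    rate_max: float = 2.0,
    rate_base: float = 0.2,
    directions=None,
    seed=None,
) -> TuningGroundTruth:
    """Build direction-tuning ground truth with von-Mises-shaped (orientation) tuning.

    ``kappa`` may be a scalar or per-site array; kappa=0 yields a flat curve.
    Rates are rate_base + (rate_max - rate_base) * exp(kappa (cos(2(d-pref)) - 1)).
    """
    rng = as_rng(seed)
    if directions is None:
        directions = np.arange(8) * 45.0
    directions = np.asarray(directions, dtype=float)
    kappa = np.broadcast_to(np.asarray(kappa, dtype=float), (n_sites,)).copy()
    preferred = rng.choice(directions, size=n_sites)
    dd = np.deg2rad(directions[None, :] - preferred[:, None])
    shape = np.exp(kappa[:, None] * (np.cos(2.0 * dd) - 1.0))
    rates = rate_base + (rate_max - rate_base) * shape
    rates[kappa == 0] = rate_base + (rate_max - rate_base) * 1.0  # flat at full rate
    return TuningGroundTruth(
        directions=directions, preferred_deg=preferred, concentration=kappa, rates=rates
    )


def simulate_tuned_session(
    config: SimConfig,
    tuning: TuningGroundTruth,
    kinetics: KineticParams,
    trials_per_direction: int = 15,
    stim_s: float = 2.0,
    gray_s: float = 1.0,
    spontaneous_rate: float = 0.05,
    centers=None,
    seed=None,
):
    """Simulate a drifting-grating session: randomized trial order, 2-s stimuli
    after 1-s gray, event rates set by each site's tuning curve.

    Returns (SyntheticMovie, stimulus log DataFrame with onset_s/direction_deg).
    The movie duration is derived from the trial count; ``config.duration`` is
    overridden accordingly.
    """
    if trials_per_direction < 1:
        raise ValueError("trials_per_direction must be >= 1")
    rng = as_rng(config.rng_seed if seed is None else seed)
    directions = tuning.directions
    order = np.repeat(directions, trials_per_direction)
    rng.shuffle(order)
    trial_len = gray_s + stim_s
    n_trials = order.size
    duration = n_trials * trial_len + gray_s
    cfg = SimConfig(
        frame_rate=config.frame_rate,
        duration=duration,
        image_shape=config.image_shape,
        n_sites=config.n_sites,
        footprint_sigma=config.footprint_sigma,
        baseline_photon_rate=config.baseline_photon_rate,
        site_brightness=config.site_brightness,
        bleach_tau=config.bleach_tau,
        rng_seed=config.rng_seed,
    )
    onsets = gray_s + np.arange(n_trials) * trial_len
    # snap onsets to the frame grid (sample-and-hold convention)
    onsets = np.round(onsets * cfg.frame_rate) / cfg.frame_rate

    dir_index = {d: i for i, d in enumerate(directions)}
    trains = []
    for s in range(cfg.n_sites):
        times = [simulate_release_train(spontaneous_rate, duration, seed=rng).event_times]
        for onset, d in zip(onsets, order):
            rate = tuning.rates[s, dir_index[d]]
            n = rng.poisson(rate * stim_s)
            times.append(onset + np.sort(rng.uniform(0.0, stim_s, size=n)))
        t = np.sort(np.concatenate(times))
        if t.size > 1:  # enforce strict monotonicity
            dup = np.diff(t) <= 0
            while np.any(dup):
                t[1:][dup] = np.nextafter(t[1:][dup], np.inf)
                t = np.sort(t)
                dup = np.diff(t) <= 0
        trains.append(ReleaseTrain(site_id=s, event_times=t[t < duration]))

    movie = render_movie(cfg, trains, kinetics, centers=centers)
    movie.ground_truth["tuning"] = tuning
    log = pd.DataFrame({"onset_s": onsets, "direction_deg": order})
    return movie, log


def simulate_sparse_noise_stimulus(
    n_frames: int,
    grid_shape: tuple[int, int],
    p_nongray: float = 0.02,
    refresh_rate: float = 5.0,
    seed=None,
) -> SparseNoiseStimulus:
    """Sparse-noise frames: each cell independently non-gray with probability
    ``p_nongray``; black and white equiprobable given non-gray."""
    if not 0.0 <= p_nongray <= 1.0:
        raise ValueError("p_nongray must lie in [0, 1]")
    check_positive(refresh_rate, "refresh_rate")
    rng = as_rng(seed)
    u = rng.random((n_frames, *grid_shape))
    sign = np.where(rng.random((n_frames, *grid_shape)) < 0.5, 1, -1).astype(np.int8)
    frames = np.where(u < p_nongray, sign, 0).astype(np.int8)
    return SparseNoiseStimulus(frames=frames, refresh_rate=refresh_rate, p_nongray=p_nongray)


def simulate_sparse_noise_session(
    stimulus: SparseNoiseStimulus,
    rf_on: np.ndarray,
    rf_off: np.ndarray,
    noise_sd: float,
    frame_rate: float,
    seed=None,
):
    """Linear responses to a sparse-noise stimulus through known ON/OFF RFs.

    ``rf_on``/``rf_off`` have shape (n_sites, gridY, gridX, n_lags) with the lag
    grid at the response ``frame_rate``. The stimulus is upsampled by
    sample-and-hold; response = X @ w + Gaussian noise, using the same lagged
    design convention as the RF estimator, so noiseless recovery is exact.

    Returns (responses (n_sites, T), design) where design is the lagged
    stimulus design matrix object.
    """
    from .strf import DesignMatrix, build_design

    rf_on = np.asarray(rf_on, dtype=float)
    rf_off = np.asarray(rf_off, dtype=float)
    if rf_on.shape != rf_off.shape:
        raise ValueError("rf_on and rf_off must have identical shapes")
    n_sites, gy, gx, n_lags = rf_on.shape
    if (gy, gx) != stimulus.frames.shape[1:]:
        raise ValueError("RF grid does not match stimulus grid")
    max_lag = (n_lags - 1) / frame_rate
    if max_lag > 1.4 + 1e-9:
        raise ValueError("RF lag span exceeds 1.4 s")
    design: DesignMatrix = build_design(stimulus, frame_rate, max_lag=max_lag)
    w = np.concatenate(
        [rf_on.reshape(n_sites, -1), rf_off.reshape(n_sites, -1)], axis=1
    )  # matches (block, pixel, lag) column order
    clean = design.X @ w.T  # T x n_sites
    rng = as_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean
    return noisy.T.copy(), design


def simulate_photometry(
    duration: float,
    reward_times,
    kinetics: KineticParams,
    drift_poly_coeffs=(1.0,),
    bleach_tau: float | None = None,
    noise_sd: float = 0.0,
    rate_hz: float = 100.0,
    seed=None,
):
    """Photometry trace: polynomial drift x bleach x (1 + sum of reward kernels) + noise.

    The drift polynomial is evaluated on normalized time t/duration (highest
    order first, ``np.polyval`` convention). Returns (values, event log
    DataFrame with time_s/label).
    """
    check_positive(duration, "duration")
    check_positive(rate_hz, "rate_hz")
    reward_times = np.asarray(reward_times, dtype=float)
    if reward_times.size and (reward_times.min() < 0 or reward_times.max() >= duration):
        raise ValueError("reward_times must lie within [0, duration)")
    T = int(round(duration * rate_hz))
    t = np.arange(T) / rate_hz
    drift = np.polyval(np.asarray(drift_poly_coeffs, dtype=float), t / duration)
    bleach = np.exp(-t / bleach_tau) if bleach_tau is not None else 1.0
    support = min(duration, 10.0 * kinetics.tau_decay + 5.0 * kinetics.tau_rise)
    kern = indicator_kernel(kinetics, rate_hz, support)
    impulses = np.zeros(T)
    idx = np.round(reward_times * rate_hz).astype(int)
    np.add.at(impulses, idx[(idx >= 0) & (idx < T)], 1.0)
    signal = 1.0 + np.convolve(impulses, kern)[:T]
    values = drift * bleach * signal
    if noise_sd > 0:
        values = values + as_rng(seed).normal(0.0, noise_sd, size=T)
    log = pd.DataFrame({"time_s": reward_times, "label": "reward"})
    return values, log
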