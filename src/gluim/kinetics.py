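"""Transient kinetics: dF/F, spike-triggered averaging, rise/decay fitting,
autocorrelation decay estimation and modified z-score event detection."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._utils import check_positive
from .synthgen import KineticParams

__all__ = [
    "Trace",
    "STAResult",
    "TransientFit",
    "DecayEstimate",
    "compute_dff",
    "spike_triggered_average",
    "fit_transient",
    "decay_from_autocorrelation",
    "branch_decay",
    "detect_events_zscore",
]


@dataclass
class Trace:
    values: np.ndarray
    frame_rate: float  # Hz
    t_start: float = 0.0  # s of sample 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        check_positive(self.frame_rate, "frame_rate")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.values.size) / self.frame_rate

    def __len__(self) -> int:
        return self.values.size


@dataclass
class STAResult:
    mean: Trace
    sem: np.ndarray
    n_used: int

    @property
    def empty(self) -> bool:
        return self.n_used == 0


@dataclass
class TransientFit:
    params: KineticParams
    amplitude: float  # peak of the fitted curve
    time_to_peak: float  # s, peak time minus t0
    rss: float
    converged: bool
    message: str = ""

    def to_record(self) -> dict:
        return {
            "A": self.params.amplitude,
            "t0_s": self.params.t0,
            "tau_rise_s": self.params.tau_rise,
            "tau_decay_s": self.params.tau_decay,
            "amplitude": self.amplitude,
            "time_to_peak_s": self.time_to_peak,
            "rss": self.rss,
            "converged": self.converged,
        }


@dataclass
class DecayEstimate:
    tau: float | None  # s; None when undefined
    n_windows_used: int
    p_value: float | None = None  # p of the selected window's linear fit
    window_taus: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def defined(self) -> bool:
        return self.tau is not None


class DegenerateBaselineError(ValueError):
    """Raised when a baseline estimate is nonpositive or has zero spread."""


def _moving_median(x: np.ndarray, window: int) -> np.ndarray:
    # centered window, truncated (shrinking) at the edges
    return (
        pd.Series(x).rolling(window=window, center=True, min_periods=1).median().to_numpy()
    )


def compute_dff(
    trace: Trace,
    mode: str = "moving_median",
    window_frames: int = 10001,
    baseline_span: float | None = None,
) -> Trace:
    """dF/F = (F - F0)/F0.

    ``moving_median`` mode takes F0 as a centered moving median of F
    (default window 10,001 frames, edge windows truncated). ``baseline_mean``
    mode takes F0 as the mean of the first ``baseline_span`` seconds.
    """
    x = trace.values
    if x.size < 3:
        raise ValueError("trace too short for dF/F")
    if mode == "moving_median":
        if window_frames % 2 == 0:
            raise ValueError("window_frames must be odd")
        f0 = _moving_median(x, window_frames)
    elif mode == "baseline_mean":
        if baseline_span is None:
            raise ValueError("baseline_span required for baseline_mean mode")
        n = max(1, int(round(baseline_span * trace.frame_rate)))
        f0 = np.full_like(x, x[:n].mean())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.any(f0 <= 0):
        raise DegenerateBaselineError("baseline F0 is nonpositive somewhere")
    return Trace((x - f0) / f0, trace.frame_rate, trace.t_start)


def isolated_spikes(spike_times, isolation: float = 0.5) -> np.ndarray:
    """Spikes with no neighbor within ``isolation`` seconds on either side."""
    t = np.sort(np.asarray(spike_times, dtype=float))
    if t.size == 0:
        return t
    ok = np.ones(t.size, dtype=bool)
    ok[1:] &= np.diff(t) > isolation
    ok[:-1] &= np.diff(t) > isolation
    return t[ok]


def spike_triggered_average(
    dff: Trace,
    spike_times,
    pre: float,
    post: float,
    isolation: float = 0.5,
) -> STAResult:
    """Average dF/F snippets aligned at isolated spikes.

    Only spikes separated by more than ``isolation`` seconds from both the
    preceding and following spike are used. Spikes whose window falls outside
    the trace are dropped. Zero qualifying spikes yields an empty result,
    not an exception.
    """
    if pre < 0 or post < 0:
        raise ValueError("pre and post must be >= 0")
    fr = dff.frame_rate
    npre, npost = int(round(pre * fr)), int(round(post * fr))
    snippets = []
    for t in isolated_spikes(spike_times, isolation):
        k = int(round((t - dff.t_start) * fr))
        if k - npre < 0 or k + npost + 1 > len(dff):
            continue
        snippets.append(dff.values[k - npre : k + npost + 1])
    n = len(snippets)
    if n == 0:
        empty = Trace(np.zeros(npre + npost + 1), fr, -npre / fr)
        return STAResult(mean=empty, sem=np.zeros(npre + npost + 1), n_used=0)
    arr = np.asarray(snippets)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(arr.shape[1])
    return STAResult(mean=Trace(arr.mean(axis=0), fr, -npre / fr), sem=sem, n_used=n)


def _transient(t, A, t0, tau_rise, tau_decay):
    dt = t - t0
    out = A * (1.0 - np.exp(-dt / tau_rise)) * np.exp(-dt / tau_decay)
    return np.where(dt > 0, out, 0.0)


def fit_transient(sta: Trace, t0_known: float | None = None) -> TransientFit:
    """Nonlinear least-squares fit of the rise/decay transient to an STA.

    Initialization: t0 at the 10%-of-peak rise crossing, tau_rise = 2 frames,
    tau_decay from the 1/e point after the peak, A = peak. All parameters are
    bounded positive (t0 bounded to the trace span). Non-convergence is
    reported via ``converged=False``, never silently.
    """
    y = sta.values
    t = sta.times
    peak_idx = int(np.argmax(y))
    peak = y[peak_idx]
    if peak <= 0:
        raise ValueError("STA peak must be positive")
    dt = 1.0 / sta.frame_rate

    # initialization heuristics
    above = np.nonzero(y[: peak_idx + 1] >= 0.1 * peak)[0]
    t0_init = t[above[0]] - dt if above.size else t[0]
    tau_rise_init = 2.0 * dt
    post = y[peak_idx:]
    below = np.nonzero(post <= peak / np.e)[0]
    tau_decay_init = below[0] * dt if below.size else (t[-1] - t[peak_idx])
    tau_decay_init = max(tau_decay_init, dt)

    if t0_known is not None:
        def model(tt, A, tau_rise, tau_decay):
            return _transient(tt, A, t0_known, tau_rise, tau_decay)

        p0 = [peak, tau_rise_init, tau_decay_init]
        bounds = ([0.0, dt * 1e-3, dt * 1e-3], [np.inf, np.inf, np.inf])
    else:
        model = _transient
        p0 = [peak, max(t0_init, t[0]), tau_rise_init, tau_decay_init]
        bounds = ([0.0, t[0] - dt, dt * 1e-3, dt * 1e-3], [np.inf, t[-1], np.inf, np.inf])

    converged, message = True, ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:  # non-convergence
        popt, converged, message = np.asarray(p0), False, str(exc)

    if t0_known is not None:
        A, tau_rise, tau_decay = popt
        t0 = t0_known
    else:
        A, t0, tau_rise, tau_decay = popt
    params = KineticParams(amplitude=A, tau_rise=tau_rise, tau_decay=tau_decay, t0=t0)
    rss = float(np.sum((y - _transient(t, A, t0, tau_rise, tau_decay)) ** 2))
    return TransientFit(
        params=params,
        amplitude=params.peak,
        time_to_peak=params.time_to_peak,
        rss=rss,
        converged=converged,
        message=message,
    )


def _window_decay_tau(x: np.ndarray, frame_rate: float, max_lag_frames: int, alpha: float):
    """Tau from one window: robust log-linear fit to the positive-prefix
    autocorrelation; returns (tau, p) or (None, None)."""
    import statsmodels.api as sm

    x = x - x.mean()
    v = np.dot(x, x)
    if v <= 0:
        return None, None
    n = x.size
    ac = np.array([np.dot(x[:-k], x[k:]) / v for k in range(1, max_lag_frames + 1)])
    # fit only the contiguous prefix where the autocorrelation stays above
    # e^-2 of its lag-1 value; deeper lags are noise-dominated and distort
    # the log-linear fit
    floor = max(0.0, ac[0] * np.exp(-2.0))
    bad = np.nonzero(ac <= floor)[0]
    stop = bad[0] if bad.size else ac.size
    if stop < 5:
        return None, None
    lags_s = np.arange(1, stop + 1) / frame_rate
    X = sm.add_constant(lags_s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.RLM(np.log(ac[:stop]), X, M=sm.robust.norms.HuberT()).fit()
    slope, p = res.params[1], res.pvalues[1]
    if p >= alpha or slope >= 0:
        return None, None
    return abs(1.0 / slope), p


def decay_from_autocorrelation(
    dff: Trace,
    window: float = 10.0,
    max_lag: float | None = None,
    alpha: float = 0.001,
    summary: str = "min",
) -> DecayEstimate:
    """Decay time-constant from windowed autocorrelation.

    The trace is split into non-overlapping ``window``-second segments. In
    each, the autocorrelation (normalized by lag-0 variance) is computed at
    1-frame lag increments up to ``max_lag`` (default min(1 s, window/4)); a
    robust (Huber IRLS) linear fit of log-autocorrelation versus lag gives a
    slope whose t-test must reach p < ``alpha``; tau = |1/slope|. Across
    significant windows the summary is the minimum (default, robust to event
    bursts) or the median.
    """
    if max_lag is None:
        max_lag = min(1.0, window / 4.0)
    if max_lag >= window:
        raise ValueError("max_lag must be smaller than window")
    fr = dff.frame_rate
    wlen = int(round(window * fr))
    L = max(2, int(round(max_lag * fr)))
    taus, ps = [], []
    for start in range(0, len(dff) - wlen + 1, wlen) or [0]:
        seg = dff.values[start : start + wlen]
        if seg.size <= L:
            continue
        tau, p = _window_decay_tau(seg, fr, L, alpha)
        if tau is not None:
            taus.append(tau)
            ps.append(p)
    if not taus:
        return DecayEstimate(tau=None, n_windows_used=0)
    taus = np.asarray(taus)
    if summary == "min":
        k = int(np.argmin(taus))
    elif summary == "median":
        k = int(np.argsort(taus)[taus.size // 2])
    else:
        raise ValueError(f"unknown summary {summary!r}")
    return DecayEstimate(
        tau=float(taus[k]), n_windows_used=taus.size, p_value=float(ps[k]), window_taus=taus
    )


def branch_decay(estimates) -> DecayEstimate:
    """Branch-level decay: the minimum defined tau across sources."""
    defined = [e for e in estimates if e.defined]
    if not defined:
        return DecayEstimate(tau=None, n_windows_used=0)
    best = min(defined, key=lambda e: e.tau)
    return DecayEstimate(tau=best.tau, n_windows_used=len(defined), p_value=best.p_value)


def detect_events_zscore(
    dff: Trace,
    baseline_span: float = 0.5,
    threshold_sd: float = 8.0,
):
    """Modified z-score event detection.

    The baseline is the ``baseline_span``-second window with the lowest
    standard deviation; z = (x - baseline mean)/baseline sd. Events are
    threshold up-crossings: one event per contiguous supra-threshold run,
    timed at run onset. Returns (event_times, z_trace).
    """
    x = dff.values
    w = int(round(baseline_span * dff.frame_rate))
    if w < 2 or w > x.size:
        raise ValueError("baseline_span incompatible with trace length")
    s = pd.Series(x)
    stds = s.rolling(w).std(ddof=1).to_numpy()[w - 1 :]
    k = int(np.nanargmin(stds))
    base = x[k : k + w]
    mu, sd = base.mean(), base.std(ddof=1)
    if sd == 0:
        raise DegenerateBaselineError("baseline window has zero standard deviation")
    z = (x - mu) / sd
    above = z > threshold_sd
    onsets = np.nonzero(above & ~np.concatenate([[False], above[:-1]]))[0]
    event_times = dff.t_start + onsets / dff.frame_rate
    return event_times, Trace(z, dff.frame_rate, dff.t_start)
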