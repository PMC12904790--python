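"""Spontaneous-release ("optical mini") analysis: pixelwise activity images,
site detection via seeded nonnegative factorization, per-site SNR/decay
scoring and two-level well aggregation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats
from scipy.optimize import curve_fit

from ._utils import check_positive

__all__ = [
    "ActivityImage",
    "SiteMap",
    "SiteScore",
    "activity_image",
    "detect_sites",
    "spectral_noise_sd",
    "site_snr",
    "site_decay",
    "aggregate_wells",
]


@dataclass
class ActivityImage:
    statistic: np.ndarray  # per-pixel, dimensionless; expectation 1 for pure shot noise
    highpass_cutoff: float  # Hz


@dataclass
class SiteMap:
    footprints: np.ndarray  # n_sites x rows x cols, nonnegative, unit peak
    traces: np.ndarray  # n_sites x T, dF-like, nonnegative
    centroids: np.ndarray  # n_sites x 2 (row, col)

    @property
    def n_sites(self) -> int:
        return self.footprints.shape[0]


@dataclass
class SiteScore:
    site_id: int
    snr: float
    decay_tau: float | None
    n_peaks_used: int


def activity_image(movie: np.ndarray, frame_rate: float, highpass_cutoff: float = 4.0) -> ActivityImage:
    """Pixelwise activity statistic: temporal skewness of the highpass-filtered
    series, in units of the shot-noise-expected skewness 1/sqrt(mean intensity)
    (i.e. sample skewness times sqrt of the temporal mean of the raw series).
    For a pure Poisson movie the expectation is 1; values above 1 indicate
    positive skewness in excess of shot noise.

    The highpass filter subtracts a zero-phase Butterworth low-pass at
    ``highpass_cutoff`` (default 4 Hz). Pixels with nonpositive mean or zero
    variance return 0.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.shape[0] < 100:
        raise ValueError("movie must have at least 100 frames")
    check_positive(frame_rate, "frame_rate")
    mean_img = movie.mean(axis=0)
    nyq = frame_rate / 2.0
    if highpass_cutoff <= 0 or highpass_cutoff >= nyq:
        raise ValueError("highpass_cutoff must lie in (0, frame_rate/2)")
    b, a = signal.butter(2, highpass_cutoff / nyq, btype="low")
    hp = movie - signal.filtfilt(b, a, movie, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skew of constant series -> nan
        sk = stats.skew(hp, axis=0, bias=False)
    stat = np.zeros_like(mean_img)
    ok = (mean_img > 0) & np.isfinite(sk)
    if np.any(mean_img <= 0):
        warnings.warn("pixels with nonpositive mean intensity set to 0", stacklevel=2)
    stat[ok] = sk[ok] * np.sqrt(mean_img[ok])
    return ActivityImage(statistic=stat, highpass_cutoff=highpass_cutoff)


def _seed_locations(act: np.ndarray, min_activity: float, max_sites: int, min_distance: int):
    sm = ndimage.gaussian_filter(act, 1.0)
    # threshold: user floor, but never below the robust upper tail of the
    # image itself (median + 5 MAD), so pure shot-noise movies yield no seeds
    mad = 1.4826 * np.median(np.abs(act - np.median(act)))
    thresh = max(min_activity, np.median(act) + 5.0 * mad)
    # local maxima above threshold with a minimum separation
    mx = ndimage.maximum_filter(sm, size=2 * min_distance + 1, mode="nearest")
    peaks = np.argwhere((sm == mx) & (act > thresh))
    if peaks.shape[0] > max_sites:
        order = np.argsort(act[peaks[:, 0], peaks[:, 1]])[::-1]
        peaks = peaks[order[:max_sites]]
    return peaks


def detect_sites(
    movie: np.ndarray,
    frame_rate: float,
    max_sites: int = 50,
    min_activity: float = 1.5,
    footprint_sigma: float = 1.5,
    n_iter: int = 60,
    baseline_percentile: float = 20.0,
) -> SiteMap:
    """Detect localized release sites by seeded nonnegative factorization.

    The (pixels x time) dF matrix (movie minus its per-pixel temporal
    percentile baseline, clipped at 0) is factorized as W H with
    multiplicative updates. Seeds are local maxima of the activity image
    above ``min_activity``; each footprint's support is restricted to a disk
    of radius 3 x ``footprint_sigma`` around its seed, keeping sources
    spatially localized. Initialization is deterministic (seed-ordered), so
    the result is reproducible. Footprints are rescaled to unit peak.
    """
    movie = np.asarray(movie, dtype=float)
    T, rows, cols = movie.shape
    act = activity_image(movie, frame_rate).statistic
    seeds = _seed_locations(act, min_activity, max_sites, min_distance=int(np.ceil(footprint_sigma)))
    if seeds.shape[0] == 0:
        return SiteMap(
            footprints=np.zeros((0, rows, cols)),
            traces=np.zeros((0, T)),
            centroids=np.zeros((0, 2)),
        )
    # deterministic ordering: by activity, descending
    order = np.argsort(act[seeds[:, 0], seeds[:, 1]])[::-1]
    seeds = seeds[order]

    baseline = np.percentile(movie, baseline_percentile, axis=0)
    V = np.clip(movie - baseline[None], 0.0, None).reshape(T, -1).T  # pixels x time

    n = seeds.shape[0]
    rr, cc = np.mgrid[:rows, :cols]
    radius = 3.0 * footprint_sigma
    masks = np.zeros((n, rows * cols), dtype=bool)
    W = np.zeros((rows * cols, n))
    for i, (r, c) in enumerate(seeds):
        d2 = (rr - r) ** 2 + (cc - c) ** 2
        masks[i] = (d2 <= radius**2).ravel()
        W[:, i] = np.exp(-d2 / (2 * footprint_sigma**2)).ravel() * masks[i]
    H = np.maximum(W.T @ V / np.maximum((W**2).sum(axis=0)[:, None], 1e-12), 0.0)

    eps = 1e-10
    for _ in range(n_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ (H @ H.T) + eps)
        W *= masks.T  # keep supports local

    peak = W.max(axis=0)
    keep = peak > 0
    W, H, seeds = W[:, keep], H[keep], seeds[keep]
    W = W / W.max(axis=0, keepdims=True)
    H = H * peak[keep, None]
    footprints = W.T.reshape(-1, rows, cols)
    tot = footprints.sum(axis=(1, 2))
    ys = (footprints * rr[None]).sum(axis=(1, 2)) / tot
    xs = (footprints * cc[None]).sum(axis=(1, 2)) / tot
    return SiteMap(footprints=footprints, traces=H, centroids=np.stack([ys, xs], axis=1))


def spectral_noise_sd(trace: np.ndarray) -> float:
    """Noise sd from the high-frequency spectrum.

    Median amplitude of the upper third of the one-sided amplitude spectrum,
    rescaled to the sd of equal-band white noise: for white noise of sd s the
    rFFT magnitudes are Rayleigh with median s*sqrt(n ln 2).
    """
    x = np.asarray(trace, dtype=float)
    n = x.size
    amp = np.abs(np.fft.rfft(x - x.mean()))
    hi = amp[len(amp) - len(amp) // 3 :]
    return float(np.median(hi) / np.sqrt(n * np.log(2.0)))


def _find_peaks(trace: np.ndarray, frame_rate: float, noise: float):
    distance = max(1, int(round(0.05 * frame_rate)))  # 50-ms minimum separation
    idx, props = signal.find_peaks(trace, height=3.0 * noise, distance=distance)
    return idx, props.get("peak_heights", np.array([]))


def _debaseline(trace: np.ndarray) -> np.ndarray:
    # peak amplitudes are measured relative to the trace's median baseline
    trace = np.asarray(trace, dtype=float)
    return trace - np.median(trace)


def site_snr(trace: np.ndarray, frame_rate: float) -> tuple[float, int]:
    """Per-site SNR: amplitude of the third-largest detected peak divided by
    the spectral noise estimate. With fewer than three peaks the smallest
    available peak is used; with none, SNR is 0. Returns (snr, n_peaks)."""
    trace = _debaseline(trace)
    noise = spectral_noise_sd(trace)
    if noise <= 0:
        return float("nan"), 0
    _, heights = _find_peaks(trace, frame_rate, noise)
    if heights.size == 0:
        return 0.0, 0
    ordered = np.sort(heights)[::-1]
    ref = ordered[2] if ordered.size >= 3 else ordered[-1]
    return float(ref / noise), int(heights.size)


def _exp_decay(t, amp, tau, offset):
    return amp * np.exp(-t / tau) + offset


def site_decay(
    trace: np.ndarray,
    frame_rate: float,
    isolation: float | None = None,
    tau_guess: float = 0.15,
) -> tuple[float | None, int]:
    """Decay tau from the mean peak-triggered trace of isolated events.

    Isolated peaks (no neighboring peak within ``isolation``, default
    5 x a first-pass tau of 150 ms) are averaged from the peak onward over a
    5-tau span, and a single exponential (with offset) is fit by least
    squares. One refinement pass re-applies the isolation criterion with the
    fitted tau. Returns (tau_s or None, n_peaks_used).
    """
    trace = _debaseline(trace)
    noise = spectral_noise_sd(trace)
    if noise <= 0:
        return None, 0

    def one_pass(tau_ref: float):
        iso = isolation if isolation is not None else 5.0 * tau_ref
        idx, heights = _find_peaks(trace, frame_rate, noise)
        # trigger averaging only on clear events (5 sigma): spurious noise
        # maxima would both break isolation and flatten the mean decay
        idx = idx[heights >= 5.0 * noise]
        if idx.size == 0:
            return None, 0
        iso_frames = iso * frame_rate
        good = np.ones(idx.size, dtype=bool)
        if idx.size > 1:
            good[1:] &= np.diff(idx) > iso_frames
            good[:-1] &= np.diff(idx) > iso_frames
        sel = idx[good]
        span = max(3, int(round(5.0 * tau_ref * frame_rate)))
        snippets = [trace[k : k + span] for k in sel if k + span <= trace.size]
        if not snippets:
            return None, 0
        mean = np.mean(snippets, axis=0)
        # skip the flat top: residual rise-term curvature right after the
        # peak biases the exponential fit; start once below 90% of the peak
        drop = np.nonzero(mean < 0.9 * mean[0])[0]
        start = min(drop[0], mean.size // 4) if drop.size else 0
        mean = mean[start:]
        t = np.arange(mean.size) / frame_rate
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _exp_decay,
                    t,
                    mean,
                    p0=[max(mean[0], noise), tau_ref, 0.0],
                    bounds=([0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                    maxfev=10000,
                )
        except RuntimeError:
            return None, len(snippets)
        return float(popt[1]), len(snippets)

    tau, n = one_pass(tau_guess)
    if tau is None:
        return None, n
    tau2, n2 = one_pass(tau)  # refinement with the bootstrapped tau
    return (tau2, n2) if tau2 is not None else (tau, n)


def aggregate_wells(scores: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-level aggregation of site scores.

    ``scores`` needs columns well, variant and one or more numeric metrics
    (e.g. snr, decay_tau). Per well the median of each metric across sites is
    taken; per variant the mean and SEM of the well medians. Empty wells are
    simply absent from the input; rows with NaN metrics are ignored per
    metric. Returns (well_table, variant_table).
    """
    metric_cols = [c for c in scores.columns if c not in ("well", "variant", "site_id")]
    grouped = scores.groupby(["variant", "well"])[metric_cols].median().reset_index()
    var = grouped.groupby("variant")[metric_cols].agg(["mean", "sem", "count"])
    var.columns = ["_".join(c) for c in var.columns]
    return grouped, var.reset_index()
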