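"""Direction/orientation tuning statistics and the cross-validated pixel-pair
covariance measure of spatial signal spread.

Orientation statistics use the doubled-angle convention: each of the 8
direction responses contributes a vector at twice its orientation angle
(direction mod 180), so opposite drift directions reinforce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb

from ._utils import as_rng

__all__ = [
    "TimeResolvedTuning",
    "OrientationStats",
    "SpreadCurve",
    "time_resolved_tuning",
    "eight_point_tuning",
    "orientation_stats",
    "tuning_map",
    "pixel_pairs",
    "cv_pair_covariance",
    "spread_curve",
    "crossval_spread",
]


@dataclass
class TimeResolvedTuning:
    directions: np.ndarray  # degrees, sorted unique
    traces: np.ndarray  # n_directions x ... x L mean traces (pre + on window)
    n_pre: int  # samples before stimulus onset
    frame_rate: float


@dataclass
class OrientationStats:
    preferred_deg: np.ndarray  # in [0, 180); nan when undefined
    osi: np.ndarray  # normalized variant: resultant length / sum of responses
    osi_raw: np.ndarray  # raw variant: magnitude of the vector sum
    tuning_magnitude: np.ndarray  # 2-norm of the tuning curve
    response_amplitude: np.ndarray  # mean response magnitude


@dataclass
class SpreadCurve:
    distance: np.ndarray
    mean: np.ndarray  # per-bin mean cross-validated statistic
    d_1e: float | None
    d_1e2: float | None
    ci_d_1e: tuple | None = None
    ci_d_1e2: tuple | None = None
    statistic: str = "covariance"


def _trial_snippets(values, frame_rate, stim_log, stim_s, pre_s):
    """(..., n_trials, L) snippets aligned to stimulus onsets, plus labels."""
    values = np.asarray(values, dtype=float)
    onsets = np.asarray(stim_log["onset_s"], dtype=float)
    dirs = np.asarray(stim_log["direction_deg"], dtype=float)
    n_pre = int(round(pre_s * frame_rate))
    n_on = int(round(stim_s * frame_rate))
    T = values.shape[-1]
    keep, snips = [], []
    for i, onset in enumerate(onsets):
        k = int(round(onset * frame_rate))
        if k - n_pre < 0 or k + n_on > T:
            continue
        keep.append(i)
        snips.append(values[..., k - n_pre : k + n_on])
    snips = np.stack(snips, axis=-2)  # (..., n_trials, L)
    return snips, dirs[keep], n_pre


def time_resolved_tuning(
    values,
    frame_rate: float,
    stim_log: pd.DataFrame,
    stim_s: float = 2.0,
    pre_s: float = 0.5,
) -> TimeResolvedTuning:
    """Per-direction trial-mean traces over the stimulus window.

    ``values`` is a dF/F array whose last axis is time; leading axes (e.g.
    pixels) are preserved. Each trace spans ``pre_s`` before onset through the
    ``stim_s`` stimulus. Directions with no trials are absent from the result
    (never zero-filled).
    """
    snips, dirs, n_pre = _trial_snippets(values, frame_rate, stim_log, stim_s, pre_s)
    uniq = np.unique(dirs)
    traces = np.stack([snips[..., dirs == d, :].mean(axis=-2) for d in uniq])
    return TimeResolvedTuning(directions=uniq, traces=traces, n_pre=n_pre, frame_rate=frame_rate)


def eight_point_tuning(tr: TimeResolvedTuning, pre_window: float = 0.5) -> np.ndarray:
    """Per-direction scalar response: mean over the on period minus the mean
    over the ``pre_window`` seconds before the stimulus."""
    n_base = int(round(pre_window * tr.frame_rate))
    if n_base < 1 or n_base > tr.n_pre:
        raise ValueError("pre_window exceeds available pre-stimulus samples")
    pre = tr.traces[..., tr.n_pre - n_base : tr.n_pre].mean(axis=-1)
    on = tr.traces[..., tr.n_pre :].mean(axis=-1)
    return on - pre


def orientation_stats(responses, directions) -> OrientationStats:
    """Vector-sum orientation statistics from an eight-point tuning curve.

    Responses may have leading batch axes; the last axis matches
    ``directions``. Negative responses are rectified to 0 before vector
    summation. Two OSI variants are returned: the normalized form (resultant
    length divided by the summed responses, in [0, 1]) and the raw resultant
    magnitude. All-zero curves yield nan preferred orientation and OSI 0.
    """
    r = np.asarray(responses, dtype=float)
    d = np.asarray(directions, dtype=float)
    if np.any(r < 0):
        warnings.warn("negative tuning responses rectified to 0", stacklevel=2)
        r = np.clip(r, 0.0, None)
    ang = np.deg2rad(2.0 * (d % 180.0))
    z = (r * np.exp(1j * ang)).sum(axis=-1)
    total = r.sum(axis=-1)
    raw = np.abs(z)
    with np.errstate(invalid="ignore", divide="ignore"):
        osi = np.where(total > 0, raw / np.where(total > 0, total, 1.0), 0.0)
        pref = np.where(total > 0, np.mod(np.angle(z) / 2.0, np.pi) * 180.0 / np.pi, np.nan)
    return OrientationStats(
        preferred_deg=pref,
        osi=osi,
        osi_raw=raw,
        tuning_magnitude=np.linalg.norm(r, axis=-1),
        response_amplitude=r.mean(axis=-1),
    )


def tuning_map(preferred_deg, osi, amplitude) -> np.ndarray:
    """HSV tuning map: hue = preferred orientation / 180, saturation = OSI
    (clipped to [0, 1]), value = amplitude normalized to the field-of-view
    maximum. Returns an RGB array."""
    pref = np.nan_to_num(np.asarray(preferred_deg, dtype=float), nan=0.0)
    h = (pref % 180.0) / 180.0
    s = np.clip(np.asarray(osi, dtype=float), 0.0, 1.0)
    v = np.asarray(amplitude, dtype=float)
    vmax = v.max()
    v = v / vmax if vmax > 0 else np.zeros_like(v)
    return hsv_to_rgb(np.stack([h, s, np.clip(v, 0.0, 1.0)], axis=-1))


def labeled_mask(mean_image: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Labeled pixels: the top-``q`` quantile of the mean image, dilated by
    1 px — pixels on or near the brightest structures. The complement is the
    background set."""
    from scipy.ndimage import binary_dilation

    thresh = np.quantile(mean_image, 1.0 - q)
    return binary_dilation(mean_image >= thresh)


def pixel_pairs(mask: np.ndarray, max_dist: float = 30.0, max_pairs: int = 100_000, seed=None):
    """All pixel pairs within ``mask`` separated by at most ``max_dist``,
    subsampled to ``max_pairs``. Returns (flat index pairs (n, 2), distances)."""
    coords = np.argwhere(mask)
    flat = coords[:, 0] * mask.shape[1] + coords[:, 1]
    n = coords.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    d = np.hypot(*(coords[ii] - coords[jj]).T)
    keep = d <= max_dist
    ii, jj, d = ii[keep], jj[keep], d[keep]
    if ii.size > max_pairs:
        sel = as_rng(seed).choice(ii.size, size=max_pairs, replace=False)
        ii, jj, d = ii[sel], jj[sel], d[sel]
    return np.stack([flat[ii], flat[jj]], axis=1), d


def cv_pair_covariance(
    values,
    frame_rate: float,
    stim_log: pd.DataFrame,
    pairs: np.ndarray,
    n_splits: int = 20,
    stim_s: float = 2.0,
    pre_s: float = 0.5,
    seed=None,
):
    """Cross-validated covariance (and correlation) between pixel pairs.

    For each random mutually exclusive half-split of the trials of every
    direction, the time-resolved tuning curve of the first pixel is computed
    from one half and that of the second pixel from the other half; the
    covariance between the two curves is averaged over ``n_splits`` splits.
    Because the split halves share no trials, trial noise is independent
    between the two curves and the estimate is unbiased for the shared-signal
    covariance. Returns (cov, corr) arrays of length n_pairs.
    """
    rng = as_rng(seed)
    values = np.asarray(values, dtype=float)
    snips, dirs, n_pre = _trial_snippets(values, frame_rate, stim_log, stim_s, pre_s)
    uniq = np.unique(dirs)
    by_dir = [np.nonzero(dirs == d)[0] for d in uniq]
    if min(len(ix) for ix in by_dir) < 4:
        raise ValueError("need at least 4 trials per direction to split")
    i_idx, j_idx = pairs[:, 0], pairs[:, 1]
    cov_acc = np.zeros(pairs.shape[0])
    corr_acc = np.zeros(pairs.shape[0])
    for _ in range(n_splits):
        half_a, half_b = [], []
        for ix in by_dir:
            perm = rng.permutation(ix)
            h = len(perm) // 2
            half_a.append(perm[:h])
            half_b.append(perm[h : 2 * h])
        curves_a = np.concatenate(
            [snips[:, a, :].mean(axis=1) for a in half_a], axis=-1
        )  # (P, n_dir*L)
        curves_b = np.concatenate([snips[:, b, :].mean(axis=1) for b in half_b], axis=-1)
        ca = curves_a - curves_a.mean(axis=-1, keepdims=True)
        cb = curves_b - curves_b.mean(axis=-1, keepdims=True)
        K = ca.shape[-1]
        cov = np.einsum("ik,ik->i", ca[i_idx], cb[j_idx]) / (K - 1)
        sa = ca.std(axis=-1, ddof=1)
        sb = cb.std(axis=-1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / (sa[i_idx] * sb[j_idx])
        cov_acc += cov
        corr_acc += np.nan_to_num(corr)
    return cov_acc / n_splits, corr_acc / n_splits


def spread_curve(distances, stat_values, bin_width: float = 1.0, statistic: str = "covariance") -> SpreadCurve:
    """Bin a per-pair statistic by distance and find 1/e and 1/e^2 crossings.

    The curve maximum is its global per-bin maximum; crossing distances are
    found by linear interpolation at the first drop below max/e and max/e^2
    beyond the maximum. A crossing that never occurs within range is None.
    """
    distances = np.asarray(distances, dtype=float)
    stat_values = np.asarray(stat_values, dtype=float)
    bins = np.floor(distances / bin_width).astype(int)
    uniq = np.unique(bins)
    centers = (uniq + 0.5) * bin_width
    means = np.array([stat_values[bins == b].mean() for b in uniq])
    d1, d2 = _crossings(centers, means)
    return SpreadCurve(distance=centers, mean=means, d_1e=d1, d_1e2=d2, statistic=statistic)


def crossval_spread(
    recordings,
    n_boot: int = 1000,
    bin_width: float = 1.0,
    statistic: str = "covariance",
    seed=None,
) -> SpreadCurve:
    """Average spread curve across recordings with bootstrap CIs.

    ``recordings`` is a list of (distances, stat_values) tuples, one per
    recording (from :func:`cv_pair_covariance`). The mean curve is the
    across-recording mean of per-recording binned curves on a common grid;
    CIs for the 1/e and 1/e^2 distances are the 2.5/97.5 percentiles over
    ``n_boot`` bootstrap resamples of recordings.
    """
    per_rec = [spread_curve(d, v, bin_width, statistic) for d, v in recordings]
    grid = np.unique(np.concatenate([c.distance for c in per_rec]))

    def mean_curve(curves):
        stack = np.full((len(curves), grid.size), np.nan)
        for i, c in enumerate(curves):
            stack[i, np.searchsorted(grid, c.distance)] = c.mean
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.nanmean(stack, axis=0)

    m = mean_curve(per_rec)
    base = SpreadCurve(distance=grid, mean=m, d_1e=None, d_1e2=None, statistic=statistic)
    base.d_1e, base.d_1e2 = _crossings(grid, m)

    if len(per_rec) > 1 and n_boot > 0:
        rng = as_rng(seed)
        b1, b2 = [], []
        for _ in range(n_boot):
            pick = rng.integers(0, len(per_rec), size=len(per_rec))
            mb = mean_curve([per_rec[i] for i in pick])
            d1, d2 = _crossings(grid, mb)
            b1.append(d1)
            b2.append(d2)
        b1 = np.array([x for x in b1 if x is not None], dtype=float)
        b2 = np.array([x for x in b2 if x is not None], dtype=float)
        if b1.size:
            base.ci_d_1e = (float(np.percentile(b1, 2.5)), float(np.percentile(b1, 97.5)))
        if b2.size:
            base.ci_d_1e2 = (float(np.percentile(b2, 2.5)), float(np.percentile(b2, 97.5)))
    return base


def _crossings(x, y):
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    if y.size == 0:
        return None, None
    mx = y.max()
    out = []
    for target in (mx / np.e, mx / np.e**2):
        k0 = int(np.argmax(y))
        val = None
        for k in range(k0, y.size - 1):
            y0, y1 = y[k], y[k + 1]
            if y0 >= target > y1:
                f = (y0 - target) / (y0 - y1)
                val = float(x[k] + f * (x[k + 1] - x[k]))
                break
        out.append(val)
    return out[0], out[1]
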