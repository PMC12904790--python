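"""Fiber-photometry preprocessing and peri-event averaging."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ._utils import check_positive

__all__ = ["PETH", "detrend", "peth"]


@dataclass
class PETH:
    rel_time: np.ndarray  # s relative to event
    mean: np.ndarray
    sem: np.ndarray
    n_trials: int
    trials: np.ndarray  # n_trials x L baseline-subtracted snippets
    n_dropped: int


def detrend(
    values: np.ndarray,
    rate: float,
    lowcut_period: float = 180.0,
    poly_order: int = 4,
) -> np.ndarray:
    """Bleach-corrected, low-cut-detrended dF/F-like trace.

    A ``poly_order`` (default 4th-order) polynomial is least-squares fit to
    the raw trace and taken as the slow photobleaching baseline; the trace is
    divided by it and 1 subtracted. A Gaussian low-cut filter then removes
    residual drift: the Gaussian low-pass sd is set so its gain is 1/2 at the
    cutoff frequency 1/``lowcut_period`` (period within the 2-4 min range,
    default the 3-min midpoint), and the low-pass output is subtracted.

    An input that is exactly a ``poly_order`` polynomial returns (numerically)
    zero everywhere.
    """
    values = np.asarray(values, dtype=float)
    check_positive(rate, "rate")
    if values.size / rate <= lowcut_period:
        raise ValueError("trace must be longer than the low-cut period")
    t = np.linspace(-1.0, 1.0, values.size)  # scaled domain for conditioning
    series = np.polynomial.polynomial.Polynomial.fit(t, values, poly_order)
    baseline = series(t)
    if np.any(baseline <= 0):
        raise ValueError("polynomial baseline is nonpositive; cannot form dF/F")
    rel = values / baseline - 1.0
    fc = 1.0 / lowcut_period
    sigma_s = np.sqrt(np.log(2.0) / 2.0) / (np.pi * fc)
    slow = gaussian_filter1d(rel, sigma_s * rate, mode="reflect")
    return rel - slow


def peth(
    values: np.ndarray,
    rate: float,
    event_times,
    window: tuple[float, float] = (-2.0, 5.0),
    baseline: float = 2.0,
) -> PETH:
    """Peri-event average with local pre-event baseline subtraction.

    Each trial snippet spans ``window`` (seconds relative to the event) and
    has the mean of its ``baseline``-second pre-event period subtracted
    before averaging. Events without enough history or future samples are
    dropped (counted in ``n_dropped``).
    """
    values = np.asarray(values, dtype=float)
    check_positive(rate, "rate")
    pre, post = window
    if pre > -baseline:
        raise ValueError("window must include the full pre-event baseline period")
    n_pre = int(round(-pre * rate))
    n_post = int(round(post * rate))
    n_base = int(round(baseline * rate))
    trials, dropped = [], 0
    for t in np.asarray(event_times, dtype=float):
        k = int(round(t * rate))
        if k - n_pre < 0 or k + n_post > values.size:
            dropped += 1
            continue
        snip = values[k - n_pre : k + n_post].copy()
        snip -= snip[n_pre - n_base : n_pre].mean()
        trials.append(snip)
    if not trials:
        raise ValueError("no events with sufficient history")
    arr = np.asarray(trials)
    n = arr.shape[0]
    sem = arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(arr.shape[1])
    rel_time = (np.arange(-n_pre, n_post)) / rate
    return PETH(
        rel_time=rel_time,
        mean=arr.mean(axis=0),
        sem=sem,
        n_trials=n,
        trials=arr,
        n_dropped=dropped,
    )
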