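"""Spatiotemporal receptive-field estimation from sparse-noise stimuli.

Pipeline: lagged ON/OFF design matrix -> ridge regression with a spatial
Laplacian smoothness penalty -> threefold cross-validated lambda selection ->
full-data refit -> circular-shift permutation significance -> responsiveness
classification -> 2D-Gaussian subfield fit of the best-lag spatial slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import curve_fit

from ._utils import as_rng, check_positive

__all__ = [
    "DesignMatrix",
    "STRF",
    "GaussianFit",
    "build_design",
    "laplacian_penalty",
    "fit_strf",
    "explained_variance",
    "crossval_lambda",
    "circular_shift_test",
    "classify_responsive",
    "spatial_rf",
    "map_strf",
]


@dataclass
class DesignMatrix:
    """Lagged ON/OFF stimulus design.

    Column order is (block, pixel, lag): column b*P*nl + p*nl + l holds the
    ON (b=0) or OFF (b=1) value of grid pixel p at lag l. Row t references
    only stimulus at times <= t; rows with incomplete history are
    zero-padded.
    """

    X: np.ndarray  # T x (2 * gy * gx * n_lags), float32
    grid_shape: tuple[int, int]
    n_lags: int
    rate: float  # response sampling rate, Hz
    _gram: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    def gram(self) -> np.ndarray:
        if self._gram is None:
            self._gram = (self.X.T @ self.X).astype(float)
        return self._gram

    def unpack(self, w: np.ndarray):
        """Weight vector -> (on, off) arrays of shape (gy, gx, n_lags)."""
        gy, gx = self.grid_shape
        w2 = w.reshape(2, gy, gx, self.n_lags)
        return w2[0], w2[1]


def build_design(stimulus, response_rate: float, max_lag: float = 1.4) -> DesignMatrix:
    """Build the time-lagged Toeplitz design from a sparse-noise stimulus.

    The stimulus is resampled to ``response_rate`` by sample-and-hold, split
    into ON (max(s, 0)) and OFF (max(-s, 0)) predictors per grid cell, and
    lagged from 0 to ``max_lag`` inclusive at the response sampling grid.
    """
    check_positive(response_rate, "response_rate")
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")
    frames = np.asarray(stimulus.frames)
    refresh = float(stimulus.refresh_rate)
    Ts, gy, gx = frames.shape
    T = int(round(Ts * response_rate / refresh))
    src = np.minimum((np.arange(T) / response_rate * refresh).astype(int), Ts - 1)
    up = frames[src].reshape(T, -1).astype(np.float32)
    on = np.maximum(up, 0.0)
    off = np.maximum(-up, 0.0)
    P = gy * gx
    n_lags = int(round(max_lag * response_rate)) + 1
    X = np.zeros((T, 2 * P * n_lags), dtype=np.float32)
    for b, sig in enumerate((on, off)):
        start = b * P * n_lags
        for l in range(n_lags):
            X[l:, start + l : start + P * n_lags : n_lags] = sig[: T - l]
    return DesignMatrix(X=X, grid_shape=(gy, gx), n_lags=n_lags, rate=response_rate)


def _grid_laplacian(gy: int, gx: int) -> sparse.csr_matrix:
    """4-neighbor discrete Laplacian with replicate (Neumann) boundaries:
    L = degree - adjacency on the grid graph."""
    idx = np.arange(gy * gx).reshape(gy, gx)
    rows, cols = [], []
    for a, b in [(idx[:-1, :], idx[1:, :]), (idx[:, :-1], idx[:, 1:])]:
        rows.extend([a.ravel(), b.ravel()])
        cols.extend([b.ravel(), a.ravel()])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    A = sparse.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(gy * gx, gy * gx))
    deg = np.asarray(A.sum(axis=1)).ravel()
    return (sparse.diags(deg) - A).tocsr()


def laplacian_penalty(grid_shape: tuple[int, int], n_lags: int) -> sparse.csr_matrix:
    """L^T L for the spatial Laplacian applied independently per lag and per
    ON/OFF block, matching the design's (block, pixel, lag) column order."""
    lap = _grid_laplacian(*grid_shape)
    ltl_pix = (lap.T @ lap).tocsr()
    return sparse.kron(sparse.identity(2), sparse.kron(ltl_pix, sparse.identity(n_lags))).tocsr()


def fit_strf(design: DesignMatrix, response: np.ndarray, lam: float) -> np.ndarray:
    """Laplacian-regularized ridge fit: argmin ||y - Xw||^2 + lam ||L w||^2,
    solved through the normal equations. Returns the flat weight vector."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    y = np.asarray(response, dtype=float)
    G = design.gram() + lam * laplacian_penalty(design.grid_shape, design.n_lags).toarray()
    rhs = design.X.T @ y
    try:
        c = cho_factor(G)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular normal equations; increase lambda to regularize"
        ) from exc
    return cho_solve(c, rhs)


def explained_variance(y_test: np.ndarray, y_hat: np.ndarray) -> float:
    """EV = 1 - sum((y_test - y_hat)^2) / sum((y_test - mean(y_test))^2)."""
    y_test = np.asarray(y_test, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y_test.size < 2:
        raise ValueError("need at least 2 test samples")
    sst = np.sum((y_test - y_test.mean()) ** 2)
    if sst == 0:
        return float("nan")
    return float(1.0 - np.sum((y_test - y_hat) ** 2) / sst)


def default_lambda_grid(design: DesignMatrix, n_per_decade: int = 10, n_decades: int = 6) -> np.ndarray:
    """Logarithmic lambda grid auto-centered on the design's spectral scale
    (ratio of the Gram trace to the penalty trace)."""
    pen = laplacian_penalty(design.grid_shape, design.n_lags)
    scale = np.trace(design.gram()) / max(pen.diagonal().sum(), 1e-12)
    half = n_decades / 2.0
    return scale * np.logspace(-half, half, int(n_per_decade * n_decades) + 1)


def crossval_lambda(
    design: DesignMatrix,
    response: np.ndarray,
    lambdas=None,
    k: int = 3,
):
    """Choose lambda by k-fold cross-validation over contiguous time blocks.

    Returns (best_lambda, full-data weights refit at best lambda, per-lambda
    mean EV array, lambda grid). Fold EVs are averaged across folds.
    """
    y = np.asarray(response, dtype=float)
    T = y.size
    if lambdas is None:
        lambdas = default_lambda_grid(design)
    lambdas = np.asarray(lambdas, dtype=float)
    bounds = np.linspace(0, T, k + 1).astype(int)
    if np.any(np.diff(bounds) < 2):
        raise ValueError("cannot build k contiguous folds from this trace")
    pen = laplacian_penalty(design.grid_shape, design.n_lags).toarray()
    G_full = design.gram()
    rhs_full = design.X.T @ y
    evs = np.zeros((k, lambdas.size))
    for f in range(k):
        lo, hi = bounds[f], bounds[f + 1]
        Xte = design.X[lo:hi]
        yte = y[lo:hi]
        G_tr = G_full - (Xte.T @ Xte).astype(float)
        rhs_tr = rhs_full - Xte.T @ yte
        for i, lam in enumerate(lambdas):
            try:
                w = cho_solve(cho_factor(G_tr + lam * pen), rhs_tr)
            except np.linalg.LinAlgError:
                evs[f, i] = -np.inf
                continue
            evs[f, i] = explained_variance(yte, Xte @ w)
    mean_ev = evs.mean(axis=0)
    if not np.any(np.isfinite(mean_ev)):
        raise RuntimeError("all cross-validated EVs undefined")
    best = int(np.nanargmax(mean_ev))
    w_full = cho_solve(cho_factor(G_full + lambdas[best] * pen), rhs_full)
    return float(lambdas[best]), w_full, mean_ev, lambdas


def circular_shift_test(
    design: DesignMatrix,
    response: np.ndarray,
    best_lambda: float,
    n_shifts: int = 1000,
    min_shift: float = 5.0,
    seed=None,
) -> float:
    """Circular-shift permutation p-value for the stRF.

    The stimulus predictor is circularly shifted in time, the RF refit at the
    fixed ``best_lambda``, and the full-data EV recomputed; shifting the
    stimulus by +s is implemented as rotating the response by -s (row
    rotation is orthogonal, leaving the penalized least-squares problem
    otherwise unchanged). Shifts are drawn uniformly outside +/-``min_shift``
    seconds. p = fraction of null EVs >= the unshifted EV, floored at
    1/n_shifts so it is never 0.
    """
    if n_shifts < 2:
        raise ValueError("n_shifts must be >= 2")
    if n_shifts < 100:
        warnings.warn("n_shifts < 100 gives a coarse p-value", stacklevel=2)
    y = np.asarray(response, dtype=float)
    T = y.size
    m = int(round(min_shift * design.rate))
    if 2 * m >= T:
        raise ValueError("min_shift too large for trace duration")
    rng = as_rng(seed)
    shifts = rng.integers(m, T - m, size=n_shifts)

    pen = laplacian_penalty(design.grid_shape, design.n_lags).toarray()
    c = cho_factor(design.gram() + best_lambda * pen)
    rhs0 = design.X.T @ y
    w0 = cho_solve(c, rhs0)
    ev0 = explained_variance(y, design.X @ w0)

    idx = (np.arange(T)[:, None] + shifts[None, :]) % T  # column s: y rolled by -shift
    Y = y[idx]
    B = design.X.T @ Y  # p x n_shifts
    W = cho_solve(c, B)
    Yhat = design.X @ W
    ss_res = ((Y - Yhat) ** 2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    null_ev = 1.0 - ss_res / ss_tot
    exceed = int(np.sum(null_ev >= ev0))
    return max(exceed, 1) / n_shifts


def classify_responsive(ev_full: float, p: float) -> bool:
    """Responsive iff full-data EV > 0.1 and circular-shift p < 0.005."""
    return bool(ev_full > 0.1 and p < 0.005)


@dataclass
class GaussianFit:
    center: tuple[float, float]  # (row, col) in grid cells
    sigmas: tuple[float, float]
    angle: float  # radians
    amplitude: float
    converged: bool


def _gauss2d(coords, amp, r0, c0, sr, sc, theta, offset):
    rr, cc = coords
    ct, st = np.cos(theta), np.sin(theta)
    u = (rr - r0) * ct + (cc - c0) * st
    v = -(rr - r0) * st + (cc - c0) * ct
    return (amp * np.exp(-0.5 * ((u / sr) ** 2 + (v / sc) ** 2)) + offset).ravel()


def fit_gaussian_2d(img: np.ndarray) -> GaussianFit:
    """Elliptical 2D Gaussian least-squares fit (center, sigmas, angle, amplitude)."""
    img = np.asarray(img, dtype=float)
    rr, cc = np.mgrid[: img.shape[0], : img.shape[1]]
    k = np.unravel_index(np.argmax(np.abs(img)), img.shape)
    amp0 = img[k]
    p0 = [amp0, float(k[0]), float(k[1]), 1.0, 1.0, 0.0, 0.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gauss2d,
                (rr, cc),
                img.ravel(),
                p0=p0,
                bounds=(
                    [-np.inf, -1, -1, 0.05, 0.05, -np.pi, -np.inf],
                    [np.inf, img.shape[0], img.shape[1], img.shape[0], img.shape[1], np.pi, np.inf],
                ),
                maxfev=20000,
            )
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    amp, r0, c0, sr, sc, theta, _ = popt
    return GaussianFit(
        center=(float(r0), float(c0)),
        sigmas=(float(sr), float(sc)),
        angle=float(theta),
        amplitude=float(amp),
        converged=converged,
    )


def spatial_rf(design: DesignMatrix, weights: np.ndarray):
    """Signed combined spatial RF and its 2D-Gaussian fit.

    Combined map = (ON + (-1) * OFF) / 2 per lag, so OFF-dominated
    (light-decrement-driven) regions read negative. The best lag is the lag
    whose slice carries the largest absolute combined response. Returns
    (combined slice, best_lag_s, GaussianFit).
    """
    on, off = design.unpack(weights)
    combined = (on - off) / 2.0  # gy x gx x n_lags
    flat_lag = np.abs(combined).reshape(-1, design.n_lags).max(axis=0)
    best = int(np.argmax(flat_lag))
    sl = combined[:, :, best]
    return sl, best / design.rate, fit_gaussian_2d(sl)


@dataclass
class STRF:
    on_weights: np.ndarray  # gy x gx x n_lags
    off_weights: np.ndarray
    lam: float
    ev_cv: float
    ev_full: float
    p_shift: float
    responsive: bool
    best_lag_s: float
    spatial_slice: np.ndarray
    spatial_gaussian: GaussianFit
    lambda_grid: np.ndarray
    ev_per_lambda: np.ndarray


def map_strf(
    design: DesignMatrix,
    response: np.ndarray,
    lambdas=None,
    k: int = 3,
    n_shifts: int = 1000,
    min_shift: float = 5.0,
    seed=None,
) -> STRF:
    """Full stRF pipeline: CV lambda selection, full refit, circular-shift
    significance, responsiveness classification and spatial Gaussian fit."""
    lam, w, mean_ev, grid = crossval_lambda(design, response, lambdas=lambdas, k=k)
    y = np.asarray(response, dtype=float)
    ev_full = explained_variance(y, design.X @ w)
    p = circular_shift_test(design, y, lam, n_shifts=n_shifts, min_shift=min_shift, seed=seed)
    on, off = design.unpack(w)
    sl, best_lag, gfit = spatial_rf(design, w)
    return STRF(
        on_weights=on,
        off_weights=off,
        lam=lam,
        ev_cv=float(np.nanmax(mean_ev)),
        ev_full=ev_full,
        p_shift=p,
        responsive=classify_responsive(ev_full, p),
        best_lag_s=best_lag,
        spatial_slice=sl,
        spatial_gaussian=gfit,
        lambda_grid=grid,
        ev_per_lambda=mean_ev,
    )
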