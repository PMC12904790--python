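"""Combinatorial-mutagenesis screen modeling.

A categorical GLM relates 9-site genotypes to screen response metrics, with
optional pairwise epistatic interaction terms, case-resampling bootstrap
confidence intervals, genotype-stratified cross-validated variance explained
and interaction-magnitude versus structural-distance correlation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._utils import as_rng

__all__ = [
    "SITE_LEVELS",
    "GlmFit",
    "all_genotypes",
    "build_design",
    "fit_glm",
    "bootstrap_cis",
    "cv_variance_explained",
    "interaction_distance_correlation",
    "simulate_screen",
]

# 9 mutation sites; first level is the wild-type reference. 3*2*2*2*2*3*2*2*3
# = 1,728 combinations.
SITE_LEVELS: dict[str, list[str]] = {
    "Y31": ["WT", "Q", "E"],
    "Q34": ["WT", "A"],
    "Q98": ["WT", "F"],
    "A185": ["WT", "N"],
    "T254": ["WT", "R"],
    "K271": ["WT", "F", "G"],
    "H273": ["WT", "E"],
    "Q418": ["WT", "S"],
    "N499": ["WT", "L", "V"],
}
SITES = list(SITE_LEVELS)

# metric -> statsmodels family (log link throughout)
_FAMILIES = {
    "F0": lambda: sm.families.Poisson(),
    "dF_F0": lambda: sm.families.Poisson(),
    "T_on": lambda: sm.families.Gaussian(sm.families.links.Log()),
    "T_off": lambda: sm.families.Gaussian(sm.families.links.Log()),
}

_ZERO_FLOOR = 1e-6  # floor for log-link Gaussian responses at exactly 0


def all_genotypes() -> pd.DataFrame:
    """The complete 1,728-row genotype table (one column per site)."""
    combos = itertools.product(*SITE_LEVELS.values())
    return pd.DataFrame(combos, columns=SITES)


def _main_terms() -> list[tuple[str, str]]:
    return [(s, lv) for s in SITES for lv in SITE_LEVELS[s][1:]]


def _interaction_terms() -> list[tuple[tuple[str, str], tuple[str, str]]]:
    mains = _main_terms()
    return [
        (a, b)
        for i, a in enumerate(mains)
        for b in mains[i + 1 :]
        if a[0] != b[0]  # only across distinct sites
    ]


def build_design(table: pd.DataFrame, interactions: bool = False):
    """One-hot design with wild-type reference coding.

    Main-effect columns are indicators for each non-reference level
    ("Y31=Q", ...); interaction columns, when enabled, are products of
    non-reference level pairs at distinct sites ("Y31=Q:Q98=F"). An intercept
    column is always first. Returns (X, term_names).
    """
    mains = _main_terms()
    cols = {f"{s}={lv}": (table[s] == lv).to_numpy(float) for s, lv in mains}
    if interactions:
        for (s1, l1), (s2, l2) in _interaction_terms():
            cols[f"{s1}={l1}:{s2}={l2}"] = cols[f"{s1}={l1}"] * cols[f"{s2}={l2}"]
    names = ["Intercept"] + list(cols)
    X = np.column_stack([np.ones(len(table))] + list(cols.values()))
    return X, names


def _observed_design(table: pd.DataFrame, interactions: bool):
    """Design with never-observed (all-zero) terms dropped: a subset screen
    cannot estimate level pairs that never co-occur."""
    X, names = build_design(table, interactions)
    observed = X.any(axis=0)
    if not observed.all():
        dropped = [n for n, keep in zip(names, observed) if not keep]
        warnings.warn(f"{len(dropped)} unobserved terms dropped: {dropped[:5]}...", stacklevel=3)
        X = X[:, observed]
        names = [n for n, keep in zip(names, observed) if keep]
    return X, names


@dataclass
class GlmFit:
    metric: str
    family: str
    interactions: bool
    terms: list
    params: pd.Series
    converged: bool
    ci: pd.DataFrame | None = None  # term, estimate, ci_lo, ci_hi, significant

    def interaction_params(self) -> pd.Series:
        return self.params[self.params.index.str.contains(":")]

    def predict_wildtype(self) -> float:
        """Predicted metric for the all-WT genotype: exp(intercept) under log link."""
        return float(np.exp(self.params["Intercept"]))


def _prepare_metric(table: pd.DataFrame, metric: str) -> np.ndarray:
    y = table[metric].to_numpy(float)
    if metric == "dF_F0" and np.any(y < 0):
        y = np.clip(y, 0.0, None)  # negative responses clipped to 0
    if metric in ("T_on", "T_off") and np.any(y <= 0):
        warnings.warn(f"{metric} values <= 0 floored at {_ZERO_FLOOR}", stacklevel=3)
        y = np.maximum(y, _ZERO_FLOOR)
    return y


def _fit(X: np.ndarray, y: np.ndarray, metric: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.GLM(y, X, family=_FAMILIES[metric]()).fit()


def fit_glm(table: pd.DataFrame, metric: str, interactions: bool = False) -> GlmFit:
    """Iteratively-reweighted maximum-likelihood GLM fit of a screen metric.

    Families: Poisson/log for F0 and dF_F0, Gaussian/log for T_on and T_off.
    dF_F0 values below 0 are clipped to 0 before fitting. Rank deficiency
    raises with the aliased columns named.
    """
    if metric not in _FAMILIES:
        raise ValueError(f"unknown metric {metric!r}; expected one of {list(_FAMILIES)}")
    X, names = _observed_design(table, interactions)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        _, R = np.linalg.qr(X)
        aliased = [names[j] for j in np.nonzero(np.abs(np.diag(R)) < 1e-8)[0]]
        raise ValueError(f"design is rank deficient; aliased columns: {aliased}")
    y = _prepare_metric(table, metric)
    res = _fit(X, y, metric)
    return GlmFit(
        metric=metric,
        family=type(_FAMILIES[metric]()).__name__ + "/log",
        interactions=interactions,
        terms=names,
        params=pd.Series(res.params, index=names),
        converged=bool(res.converged),
    )


def bootstrap_cis(
    table: pd.DataFrame,
    metric: str,
    interactions: bool = False,
    n_boot: int = 1000,
    seed=None,
) -> GlmFit:
    """Case-resampling bootstrap percentile 95% CIs for every coefficient.

    Rows are resampled with replacement (N draws from N rows) and the model
    refit per resample; CIs are the 2.5/97.5 percentiles. A resample whose
    fit fails is redrawn (count recorded via warning). A coefficient is
    significant iff its CI excludes 0.
    """
    rng = as_rng(seed)
    fit = fit_glm(table, metric, interactions)
    X, names = _observed_design(table, interactions)
    y = _prepare_metric(table, metric)
    n = len(table)
    draws = np.empty((n_boot, len(names)))
    redraws = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            res = _fit(X[idx], y[idx], metric)
        except Exception:
            redraws += 1
            if redraws > 10 * n_boot:
                raise RuntimeError("bootstrap resamples repeatedly failed to fit")
            continue
        draws[b] = res.params
        b += 1
    if redraws:
        warnings.warn(f"{redraws} bootstrap resamples redrawn after fit failure", stacklevel=2)
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    fit.ci = pd.DataFrame(
        {
            "term": names,
            "estimate": fit.params.to_numpy(),
            "ci_lo": lo,
            "ci_hi": hi,
            "significant": (lo > 0) | (hi < 0),
        }
    )
    return fit


def _genotype_key(table: pd.DataFrame) -> pd.Series:
    return table[SITES].agg("|".join, axis=1)


def cv_variance_explained(
    table: pd.DataFrame,
    metric: str,
    interactions: bool = False,
    k: int = 5,
    seed=None,
) -> float:
    """Cross-validated variance explained with genotype-stratified folds.

    All replicates of a genotype stay in the same fold. Out-of-fold
    predictions are pooled and scored as 1 - SSE/SST. Folds whose fit fails
    are skipped with a warning.
    """
    rng = as_rng(seed)
    key = _genotype_key(table)
    genos = key.unique()
    rng.shuffle(genos)
    fold_of = {g: i % k for i, g in enumerate(genos)}
    folds = key.map(fold_of).to_numpy()
    X, _ = _observed_design(table, interactions)
    y = _prepare_metric(table, metric)
    pred = np.full(len(table), np.nan)
    for f in range(k):
        te = folds == f
        try:
            res = _fit(X[~te], y[~te], metric)
        except Exception:
            warnings.warn(f"fold {f} failed to fit; skipped", stacklevel=2)
            continue
        pred[te] = res.predict(X[te])
    ok = np.isfinite(pred)
    sst = np.sum((y[ok] - y[ok].mean()) ** 2)
    return float(1.0 - np.sum((y[ok] - pred[ok]) ** 2) / sst)


def site_pair_distances(coords: pd.DataFrame) -> pd.DataFrame:
    """Minimum inter-atom Euclidean distance for every pair of the 9 sites.

    ``coords`` has columns site, x, y, z with one row per atom. Site pairs
    with missing coordinates are excluded.
    """
    pts = {s: g[["x", "y", "z"]].to_numpy(float) for s, g in coords.groupby("site")}
    rows = []
    for s1, s2 in itertools.combinations(SITES, 2):
        if s1 not in pts or s2 not in pts:
            continue
        a, b = pts[s1], pts[s2]
        d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)).min()
        rows.append({"site1": s1, "site2": s2, "distance": float(d)})
    return pd.DataFrame(rows)


def interaction_distance_correlation(fit: GlmFit, coords: pd.DataFrame):
    """Pearson correlation between |pairwise interaction coefficient| and the
    minimum inter-atom distance of the residue pair. Returns (r, p)."""
    if not fit.interactions:
        raise ValueError("fit has no interaction terms")
    dist = site_pair_distances(coords)
    dmap = {(r.site1, r.site2): r.distance for r in dist.itertuples()}
    dmap.update({(b, a): d for (a, b), d in list(dmap.items())})
    mags, dists = [], []
    for term, coef in fit.interaction_params().items():
        left, right = term.split(":")
        s1, s2 = left.split("=")[0], right.split("=")[0]
        if (s1, s2) not in dmap:
            continue
        mags.append(abs(coef))
        dists.append(dmap[(s1, s2)])
    r, p = stats.pearsonr(mags, dists)
    return float(r), float(p)


def simulate_screen(
    n_genotypes: int = 300,
    reps: int = 4,
    metric: str = "dF_F0",
    main_sd: float = 0.3,
    interaction_sd: float = 0.2,
    interaction_fraction: float = 0.1,
    baseline: float = 50.0,
    noise_sd: float = 0.1,
    seed=None,
):
    """Simulate a screen table from a known log-linear model.

    Main effects ~ N(0, main_sd) per non-reference level; interactions
    ~ N(0, interaction_sd) on a random ``interaction_fraction`` of level
    pairs (0 elsewhere). For Poisson-family metrics the response is drawn
    Poisson(baseline * exp(eta)); for Gaussian/log metrics it is
    baseline*exp(eta) plus Gaussian noise of sd ``noise_sd * baseline``.
    Returns (table, true_coefficients Series including intercept on the log
    scale).
    """
    rng = as_rng(seed)
    genos = all_genotypes().sample(n=n_genotypes, random_state=int(rng.integers(2**31)))
    table = genos.loc[genos.index.repeat(reps)].reset_index(drop=True)
    table["plate"] = 0
    table["well"] = np.arange(len(table))
    X, names = build_design(table, interactions=True)
    n_main = len(_main_terms())
    beta = np.zeros(len(names))
    beta[0] = np.log(baseline)
    beta[1 : 1 + n_main] = rng.normal(0.0, main_sd, size=n_main)
    n_inter = len(names) - 1 - n_main
    active = rng.random(n_inter) < interaction_fraction
    beta[1 + n_main :] = np.where(active, rng.normal(0.0, interaction_sd, size=n_inter), 0.0)
    mu = np.exp(X @ beta)
    if metric in ("F0", "dF_F0"):
        y = rng.poisson(mu).astype(float)
    else:
        y = mu + rng.normal(0.0, noise_sd * baseline, size=mu.size)
        y = np.maximum(y, _ZERO_FLOOR)
    table[metric] = y
    return table, pd.Series(beta, index=names)
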