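"""Distance/elevation decay models for genetic similarity and their permutation tests.

Model forms
-----------
Genetic similarity between individuals, G_ij = 1 - TVD_ij, is related to
great-circle distance d_ij (km) and elevation difference h_ij (m) by

    exponential:  G_ij = alpha + beta * exp(-lambda * d_ij) + e_ij
    linear:       G_ij = gamma + delta * x_ij + eps_ij,   x in {d, h}

The exponential form describes the steep rise of similarity at short
distances seen under the panel that includes local donor groups; the linear
form describes the external-panel distance trend and the elevation trend
under both panels.  When x = h, pairs with h >= 2500 m are excluded from the
linear fit to avoid undue influence from extreme-elevation outliers.

Significance is assessed by permuting individuals' birthplace records (lat,
lon and elevation move together) and, in the stratified variants, the other
shared-factor labels, while similarity stays attached to the individual.
Three exceedance rules are used, matching the analysis each belongs to:
``near_bin`` (mean G over pairs closer than 25 km), ``slope`` (the fitted
delta, more-negative-is-extreme) and ``fitted_grid`` (any fitted value on a
fixed grid of bin centers at or above the observed one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .io import pairwise_distance_km
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

NEAR_BIN_KM = 25.0
ELEV_CUTOFF_M = 2500.0
FACTORS = ["group", "language_group", "first_language", "second_language", "religion"]


@dataclass
class BinSpec:
    """Equally spaced bins for one pair variable."""

    variable: str  # "geo_km" or "elev_m"
    width: float
    centers: np.ndarray

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bin width must be positive")
        self.centers = np.asarray(self.centers, dtype=float)


GEO_GRID = BinSpec("geo_km", 25.0, np.linspace(12.5, 1187.5, 48))
ELEV_GRID = BinSpec("elev_m", 100.0, np.linspace(50.0, 2450.0, 25))


def binned_means(G: np.ndarray, x: np.ndarray, width: float) -> pd.DataFrame:
    """Mean of G within left-closed right-open bins of x.  Order-invariant."""
    G = np.asarray(G, dtype=float)
    x = np.asarray(x, dtype=float)
    idx = np.floor(x / width).astype(int)
    df = pd.DataFrame({"bin": idx, "G": G}).groupby("bin")["G"].agg(["mean", "count"])
    df["center"] = (df.index + 0.5) * width
    return df.reset_index()[["center", "mean", "count"]]


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, best_lambda: float):
        super().__init__(message)
        self.best_lambda = best_lambda


@dataclass
class DecayFit:
    model: str  # "exponential" or "linear"
    params: dict
    fitted: np.ndarray
    residuals: np.ndarray
    n_pairs: int
    n_excluded: int = 0

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.model == "exponential":
            return p["alpha"] + p["beta"] * np.exp(-p["lambda"] * x)
        return p["gamma"] + p["delta"] * x


def _ols_on(z: np.ndarray, G: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Simple OLS G = a + b z; returns (a, b, fitted)."""
    zbar, gbar = z.mean(), G.mean()
    dz = z - zbar
    denom = float(dz @ dz)
    if denom == 0:
        raise ValueError("constant regressor")
    b = float(dz @ (G - gbar)) / denom
    a = gbar - b * zbar
    return a, b, a + b * z


def fit_exponential(
    G: np.ndarray,
    d: np.ndarray,
    lam0: float = 0.01,
    two_stage: bool = False,
    max_iter: int = 500,
) -> DecayFit:
    """Least-squares fit of G = alpha + beta exp(-lambda d) + e.

    The decay rate is searched by Nelder-Mead over log(lambda) (keeping
    lambda positive), initialised at 0.01 / km.  By default (alpha, beta) are
    profiled out exactly by OLS at each candidate lambda, which yields the
    joint least-squares solution.  ``two_stage=True`` instead fixes alpha=0,
    beta=1 during the lambda search and runs the OLS once afterwards (a
    cruder variant that anchors lambda to the raw similarity scale).
    Non-convergence raises :class:`ConvergenceError` carrying the best lambda.
    """
    G = np.asarray(G, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.unique(d).size < 3:
        raise ValueError("need at least 3 distinct distances")

    if two_stage:
        def sse(t: np.ndarray) -> float:
            r = G - np.exp(-np.exp(t[0]) * d)
            return float(r @ r)
    else:
        def sse(t: np.ndarray) -> float:
            z = np.exp(-np.exp(t[0]) * d)
            try:
                _, _, fit = _ols_on(z, G)
            except ValueError:
                return float("inf")
            r = G - fit
            return float(r @ r)

    res = optimize.minimize(
        sse, x0=[np.log(lam0)], method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-10, "fatol": 1e-14},
    )
    lam = float(np.exp(res.x[0]))
    if not res.success:
        raise ConvergenceError(f"lambda search did not converge: {res.message}", lam)
    z = np.exp(-lam * d)
    try:
        alpha, beta, fitted = _ols_on(z, G)
    except ValueError:  # lambda ran off to a degenerate flat regressor
        alpha, beta, fitted = float(G.mean()), 0.0, np.full_like(G, G.mean())
    return DecayFit(
        "exponential",
        {"alpha": alpha, "beta": beta, "lambda": lam},
        fitted,
        G - fitted,
        G.size,
    )


def fit_linear(
    G: np.ndarray,
    x: np.ndarray,
    elevation_cutoff: float | None = None,
) -> DecayFit:
    """OLS fit of G = gamma + delta x + eps.

    With ``elevation_cutoff`` (meters), pairs with x >= cutoff are excluded
    from the fit; the excluded count is logged and recorded.  Fitted values
    and residuals are reported for the retained pairs only.
    """
    G = np.asarray(G, dtype=float)
    x = np.asarray(x, dtype=float)
    keep = np.ones(x.size, dtype=bool)
    if elevation_cutoff is not None:
        keep = x < elevation_cutoff
        n_out = int((~keep).sum())
        if n_out:
            logger.info("excluded %d pairs at or above %.0f", n_out, elevation_cutoff)
    gamma, delta, fitted = _ols_on(x[keep], G[keep])
    return DecayFit(
        "linear",
        {"gamma": gamma, "delta": delta},
        fitted,
        G[keep] - fitted,
        int(keep.sum()),
        n_excluded=int((~keep).sum()),
    )


def residual_adjust(G: np.ndarray, d: np.ndarray, h: np.ndarray, target: str) -> dict:
    """Adjust similarity and one spatial variable for the other.

    ``geo_after_elev``: G is replaced by the residuals of the linear fit of G
    on h, and d by the residuals kappa of d on h, shifted so min(kappa) = 0
    (so the 25 km near-bin rule stays meaningful).  ``elev_after_geo``: G is
    replaced by the residuals of the exponential fit of G on d, and h by the
    residuals of h on d.
    """
    G, d, h = (np.asarray(v, dtype=float) for v in (G, d, h))
    if target == "geo_after_elev":
        fit_gh = fit_linear(G, h)
        _, _, h_fit_of_d = _ols_on(h, d)
        kappa = d - h_fit_of_d
        kappa = kappa - kappa.min()
        return {"G": fit_gh.residuals, "x": kappa, "fits": {"G_on_h": fit_gh}}
    if target == "elev_after_geo":
        fit_gd = fit_exponential(G, d)
        _, _, d_fit_of_h = _ols_on(d, h)
        return {"G": fit_gd.residuals, "x": h - d_fit_of_h, "fits": {"G_on_d": fit_gd}}
    raise ValueError(f"unknown target {target!r}")


# ---------------------------------------------------------------------------
# pair container
# ---------------------------------------------------------------------------


@dataclass
class CohortPairs:
    """All unordered individual pairs with similarity, geometry and factors.

    Individuals with a null birthplace or elevation are excluded up front and
    counted in ``n_dropped``.
    """

    ids: list[str]
    lat: np.ndarray
    lon: np.ndarray
    elev: np.ndarray
    G: np.ndarray  # n x n similarity
    factors: pd.DataFrame  # per-individual factor columns (may hold NaN)
    n_dropped: int = 0
    D: np.ndarray = field(init=False)
    i_idx: np.ndarray = field(init=False)
    j_idx: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.D = pairwise_distance_km(self.lat, self.lon)
        self.i_idx, self.j_idx = np.triu_indices(n, k=1)

    @property
    def g(self) -> np.ndarray:
        return self.G[self.i_idx, self.j_idx]

    @property
    def d(self) -> np.ndarray:
        return self.D[self.i_idx, self.j_idx]

    @property
    def h(self) -> np.ndarray:
        return np.abs(self.elev[self.i_idx] - self.elev[self.j_idx])

    def pair_x(self, variable: str, perm: np.ndarray | None = None) -> np.ndarray:
        """Pairwise d or h, optionally under a permutation of records."""
        i = self.i_idx if perm is None else perm[self.i_idx]
        j = self.j_idx if perm is None else perm[self.j_idx]
        if variable == "geo":
            return self.D[i, j]
        if variable == "elev":
            return np.abs(self.elev[i] - self.elev[j])
        raise ValueError(f"unknown variable {variable!r}")

    def factor_mask(self, factor: str, perm: np.ndarray | None = None) -> np.ndarray:
        """Boolean pair mask: both members share a non-null factor level."""
        col = self.factors[factor].to_numpy()
        if perm is not None:
            col = col[perm]
        a, b = col[self.i_idx], col[self.j_idx]
        return (a == b) & pd.notna(a)


def cohort_pairs(sim: SimilarityMatrix, metadata: pd.DataFrame) -> CohortPairs:
    """Build the pair container from a similarity matrix and metadata table.

    Religion recorded as "Traditional" is nulled for the shared-religion
    factor (practice varies substantially across groups), and language_group
    stays null for unclassified ethnicities.
    """
    meta = metadata.loc[[i for i in sim.ids if i in metadata.index]]
    usable = meta[meta[["lat", "lon", "elevation_m"]].notna().all(axis=1)]
    n_dropped = len(sim.ids) - len(usable)
    if n_dropped:
        logger.info("dropped %d individuals lacking birthplace or elevation", n_dropped)
    keep_idx = [sim._index[i] for i in usable.index]
    factors = usable[FACTORS].copy()
    factors.loc[factors["religion"] == "Traditional", "religion"] = pd.NA
    return CohortPairs(
        ids=list(usable.index),
        lat=usable["lat"].to_numpy(dtype=float),
        lon=usable["lon"].to_numpy(dtype=float),
        elev=usable["elevation_m"].to_numpy(dtype=float),
        G=sim.values[np.ix_(keep_idx, keep_idx)],
        factors=factors,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# permutation engines
# ---------------------------------------------------------------------------


def _stratified_permutation(
    rng: np.random.Generator, n: int, strata: np.ndarray | None
) -> np.ndarray:
    """A permutation of 0..n-1, free or shuffling only within strata.

    Singleton strata are left in place (nothing to shuffle; noted at debug
    level to keep long runs quiet).
    """
    if strata is None:
        return rng.permutation(n)
    # individuals with a null stratum label are exchangeable among themselves
    strata = np.asarray(pd.Series(strata).fillna("\0missing"))
    perm = np.arange(n)
    for s in pd.unique(strata):
        members = np.flatnonzero(strata == s)
        if members.size == 1:
            logger.debug("stratum %r has a single member; left unpermuted", s)
            continue
        perm[members] = rng.permutation(members)
    return perm


def _near_bin_stat(g, x, mask, threshold):
    sel = mask & (x < threshold)
    if not sel.any():
        return float("nan")
    return float(g[sel].mean())


def _slope_stat(g, x, mask, elevation_cutoff=None):
    if elevation_cutoff is not None:
        mask = mask & (x < elevation_cutoff)
    if mask.sum() < 3:
        return float("nan")
    try:
        _, delta, _ = _ols_on(x[mask], g[mask])
    except ValueError:
        return float("nan")
    return delta


def _grid_fit(g, x, mask, centers, elevation_cutoff=None):
    if elevation_cutoff is not None:
        mask = mask & (x < elevation_cutoff)
    if mask.sum() < 3:
        return None
    try:
        a, b, _ = _ols_on(x[mask], g[mask])
    except ValueError:
        return None
    return a + b * centers


def perm_p_near_bin(
    pairs: CohortPairs,
    n_perm: int = 1000,
    seed: int = 0,
    threshold_km: float = NEAR_BIN_KM,
    factor: str | None = None,
    fixed_factor: str | None = None,
) -> float:
    """p for elevated similarity among pairs closer than 25 km.

    Locations (and, in stratified runs, the non-fixed factors) are permuted
    as whole records; p is the proportion of permutations whose mean G over
    pairs with permuted distance < 25 km is >= the observed mean.
    """
    return _scheme_p(pairs, "geo", "near_bin", n_perm, seed, factor, fixed_factor,
                     threshold_km=threshold_km)


def perm_p_slope(
    pairs: CohortPairs,
    variable: str,
    n_perm: int = 1000,
    seed: int = 0,
    factor: str | None = None,
    fixed_factor: str | None = None,
) -> float:
    """p for a negative similarity-vs-distance slope (more negative = extreme)."""
    return _scheme_p(pairs, variable, "slope", n_perm, seed, factor, fixed_factor)


def perm_p_fitted_grid(
    pairs: CohortPairs,
    variable: str,
    grid: BinSpec | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    factor: str | None = None,
    fixed_factor: str | None = None,
) -> float:
    """p from the any-bin rule on fitted values over a fixed grid of centers."""
    return _scheme_p(pairs, variable, "fitted_grid", n_perm, seed, factor, fixed_factor,
                     grid=grid)


def _scheme_p(
    pairs: CohortPairs,
    variable: str,
    scheme: str,
    n_perm: int,
    seed: int,
    factor: str | None,
    fixed_factor: str | None,
    threshold_km: float = NEAR_BIN_KM,
    grid: BinSpec | None = None,
) -> float:
    if factor is not None and factor == fixed_factor:
        raise ValueError(
            f"fixing {factor!r} while testing it leaves 0 effective permutations"
        )
    g = pairs.g
    n = len(pairs.ids)
    x_obs = pairs.pair_x(variable)
    mask_obs = (
        pairs.factor_mask(factor) if factor is not None else np.ones(g.size, dtype=bool)
    )
    cutoff = ELEV_CUTOFF_M if variable == "elev" else None
    if grid is None:
        grid = ELEV_GRID if variable == "elev" else GEO_GRID
    if scheme == "fitted_grid":
        lo, hi = x_obs.min(), x_obs.max()
        if grid.centers.min() < lo or grid.centers.max() > hi:
            logger.warning("fitted-value grid extends beyond the observed %s range", variable)

    if scheme == "near_bin":
        obs = _near_bin_stat(g, x_obs, mask_obs, threshold_km)
        if np.isnan(obs):
            raise ValueError(f"no pair under {threshold_km} km in the observed data")
    elif scheme == "slope":
        obs = _slope_stat(g, x_obs, mask_obs, cutoff)
        if np.isnan(obs):
            raise ValueError("observed slope undefined (too few usable pairs)")
    elif scheme == "fitted_grid":
        obs = _grid_fit(g, x_obs, mask_obs, grid.centers, cutoff)
        if obs is None:
            raise ValueError("observed grid fit undefined (too few usable pairs)")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    strata = (
        pairs.factors[fixed_factor].to_numpy() if fixed_factor is not None else None
    )
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = _stratified_permutation(rng, n, strata)
        x_p = pairs.pair_x(variable, perm)
        mask_p = (
            pairs.factor_mask(factor, perm) if factor is not None
            else np.ones(g.size, dtype=bool)
        )
        if scheme == "near_bin":
            stat = _near_bin_stat(g, x_p, mask_p, threshold_km)
            hit = np.isnan(stat) or stat >= obs
        elif scheme == "slope":
            stat = _slope_stat(g, x_p, mask_p, cutoff)
            hit = np.isnan(stat) or stat <= obs
        else:
            fit_p = _grid_fit(g, x_p, mask_p, grid.centers, cutoff)
            hit = fit_p is None or bool(np.any(fit_p >= obs))
        exceed += hit
    return exceed / n_perm


def shared_factor_test(
    pairs: CohortPairs,
    variable: str,
    factor: str,
    fixed_factor: str | None = None,
    scheme: str = "near_bin",
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Association of a shared factor with similarity, given spatial structure.

    Restricts all pairs (real and permuted) to those sharing the factor, then
    applies the named exceedance rule.  With ``fixed_factor``, birthplaces
    and the other factors are permuted only within its strata, preserving
    that factor's own association with similarity.
    """
    return _scheme_p(pairs, variable, scheme, n_perm, seed, factor, fixed_factor)


# ---------------------------------------------------------------------------
# final aggregation
# ---------------------------------------------------------------------------

SCHEME_NAMES = ["free"] + [f"fix_{f}" for f in FACTORS]


def excluded_schemes(target: str) -> set[str]:
    """Permutation schemes excluded from the final max-p for a given target.

    Geographic/elevation targets drop the schemes fixing group label or first
    language (those permutations barely move birthplaces); the group, first
    language and language-group targets drop the schemes fixing group and
    first language (the two are nearly collinear, and fixing the tested
    factor itself is always impossible).
    """
    excluded = {f"fix_{target}"} if target in FACTORS else set()
    if target in {"geo", "elev"}:
        excluded |= {"fix_group", "fix_first_language"}
    elif target in {"group", "first_language", "language_group"}:
        excluded |= {"fix_group", "fix_first_language"}
    return excluded


def aggregate_final_p(p_table: dict[str, float], target: str) -> float:
    """Final p for one target: the maximum over its admissible schemes."""
    keep = {s: p for s, p in p_table.items() if s not in excluded_schemes(target)}
    if not keep:
        raise ValueError(f"no admissible permutation scheme for target {target!r}")
    return max(keep.values())
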