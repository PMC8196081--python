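"""Postprocessing of externally inferred admixture events.

Covers three small analyses downstream of haplotype-based admixture
inference: ordering genetically homogeneous clusters along their main
geographic axis, scoring whether minority admixture sources tend to be
geographically nearby ("geographic proximity score"), converting admixture
dates from generations to years (generation time 28 years, mean sampled
birth year 1975), and regressing ancient-forager (Mota-like) ancestry
proportions on spatial distance from the Mota site.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .io import AdmixtureSummary

GENERATION_YEARS = 28.0
REFERENCE_BIRTH_YEAR = 1975.0


# ---------------------------------------------------------------------------
# cluster ordering
# ---------------------------------------------------------------------------


def order_clusters(D, method: str = "mds") -> pd.Series:
    """Ordinal cluster positions along the first principal geographic axis.

    ``method="mds"`` (default) applies classical multidimensional scaling to
    the distance matrix (eigen-decomposition of the double-centered squared
    distances) and ranks clusters by the first coordinate;
    ``method="rows"`` instead treats distance-matrix rows as features and
    uses their first principal component.  The axis sign is fixed so that the
    largest-magnitude coordinate is positive, making the ordering
    deterministic up to that convention.  Positions are 1..n.
    """
    if isinstance(D, pd.DataFrame):
        names = list(D.index)
        A = D.to_numpy(dtype=float)
    else:
        A = np.asarray(D, dtype=float)
        names = list(range(A.shape[0]))
    n = A.shape[0]
    if A.shape != (n, n) or not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("need a symmetric distance matrix")
    if np.any(A < 0):
        raise ValueError("distances must be non-negative")
    offdiag = A[~np.eye(n, dtype=bool)]
    if n < 2 or np.ptp(offdiag) == 0 and offdiag.size > 1 and n > 2:
        raise ValueError("degenerate (all-equal) distance matrix has no principal axis")

    if method == "mds":
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (A**2) @ J
        w, v = linalg.eigh(B)
        coord = v[:, -1] * np.sqrt(max(w[-1], 0.0))
    elif method == "rows":
        X = A - A.mean(axis=0, keepdims=True)
        _, _, vt = linalg.svd(X, full_matrices=False)
        coord = X @ vt[0]
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.ptp(coord) == 0:
        raise ValueError("degenerate distance matrix: no principal axis")
    if coord[int(np.argmax(np.abs(coord)))] < 0:
        coord = -coord
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(coord, kind="mergesort")] = np.arange(1, n + 1)
    return pd.Series(ranks, index=names, name="position")


def cluster_geography(members: pd.DataFrame) -> pd.DataFrame:
    """Mean latitude/longitude/elevation per cluster from member metadata.

    ``members`` needs columns cluster, lat, lon, elevation_m.
    """
    return members.groupby("cluster")[["lat", "lon", "elevation_m"]].mean()


# ---------------------------------------------------------------------------
# geographic proximity score
# ---------------------------------------------------------------------------


def _circular_gap(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    raw = np.abs(a - b)
    return np.minimum(raw, n - raw)


def proximity_score(
    summaries: list[AdmixtureSummary],
    ordering: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean ordinal distance from each admixture target to its minority source.

    Positions live on a circle (ordinal distance min(|a-b|, n-|a-b|)), so the
    score is invariant to reversing or rotating the axis.  The null permutes
    the clusters' positions on the circle uniformly; p is the proportion of
    permutations with a score <= the observed one (small score = sources
    geographically nearby).
    """
    n = len(ordering)
    pos = ordering.to_dict()
    targets, sources = [], []
    for s in summaries:
        if s.cluster_id not in pos:
            raise ValueError(f"target cluster {s.cluster_id!r} missing from ordering")
        surr = s.minority_surrogate
        if surr not in pos:
            raise ValueError(f"surrogate {surr!r} missing from ordering")
        targets.append(pos[s.cluster_id])
        sources.append(pos[surr])
    t = np.asarray(targets, dtype=float)
    c = np.asarray(sources, dtype=float)
    obs = float(_circular_gap(t, c, n).mean())
    labels = np.asarray(ordering.index)
    base = ordering.to_numpy(dtype=float)
    ti = np.array([list(labels).index(s.cluster_id) for s in summaries])
    si = np.array([list(labels).index(s.minority_surrogate) for s in summaries])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm_pos = base[rng.permutation(n)]
        score = float(_circular_gap(perm_pos[ti], perm_pos[si], n).mean())
        exceed += score <= obs
    return obs, exceed / n_perm


# ---------------------------------------------------------------------------
# date conversion
# ---------------------------------------------------------------------------


def generations_to_calendar(g: float) -> float:
    """Calendar year of an admixture date g generations before sampling.

    Uses year = 1975 - 28 * (g + 1): sampled individuals were born around
    1975 and their own generation counts as one step back.
    """
    if np.any(np.asarray(g) < 0):
        raise ValueError("generations must be non-negative")
    return REFERENCE_BIRTH_YEAR - GENERATION_YEARS * (np.asarray(g, dtype=float) + 1.0)


def generations_to_elapsed(g: float, include_offset: bool = False) -> float:
    """Elapsed years for g generations: 28*g, or 28*(g+1) with the offset.

    The plain convention (default) matches the headline "years ago" figures;
    the offset variant is consistent with the calendar formula.
    """
    if np.any(np.asarray(g) < 0):
        raise ValueError("generations must be non-negative")
    gg = np.asarray(g, dtype=float)
    out = GENERATION_YEARS * (gg + 1.0) if include_offset else GENERATION_YEARS * gg
    return float(out) if out.ndim == 0 else out


def percentage(count: float, total: float, ndigits: int = 1) -> float:
    """A count expressed as a rounded percentage of a total."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


# ---------------------------------------------------------------------------
# Mota-ancestry distance regression
# ---------------------------------------------------------------------------


def mota_distance_regression(
    proportions: pd.Series,
    geo_km: pd.Series,
    elev_diff_m: pd.Series,
) -> pd.DataFrame:
    """OLS of ancestry proportion on geographic and elevation distance.

    Returns one row per covariate (plus intercept) with slope and two-sided
    p.  Distances are to a fixed reference point (the Mota discovery site).
    """
    import statsmodels.api as sm

    df = pd.concat(
        {"proportion": proportions, "geo_km": geo_km, "elev_m": elev_diff_m}, axis=1
    ).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 clusters")
    for col in ("geo_km", "elev_m"):
        if np.ptp(df[col].to_numpy(dtype=float)) == 0:
            raise ValueError(f"constant covariate {col!r}")
    X = sm.add_constant(df[["geo_km", "elev_m"]])
    res = sm.OLS(df["proportion"], X).fit()
    return pd.DataFrame({"slope": res.params, "p_value": res.pvalues})
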