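"""Cultural similarity scores and their association with genetic similarity.

Two cultural scores are computed between every pair of groups from a
group x trait table with states Y (practices), N (does not) and U
(unreported): the unweighted score counts traits whose states match as Y-Y
or N-N; the weighted score gives a Y-Y match on a trait practiced by H
groups a contribution 1/H (and an N-N match 1/Z, Z = number of N-reporting
groups), down-weighting ubiquitous practices.  U never contributes.

Association with genetic similarity uses Mantel and partial Mantel
permutation tests on the group-level matrices; per-trait category tests
compare mean pairwise genetic similarity among practicing vs non-practicing
(or unreported) groups; and recent intermixing between trait-sharing groups
is probed through atypically long shared MRCA segments.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import pairwise_distance_km
from .similarity import SimilarityMatrix
from .spatial import _ols_on, fit_exponential

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cultural scores
# ---------------------------------------------------------------------------


def cultural_scores(traits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise (unweighted, weighted) cultural similarity matrices.

    Diagonals are 0 by convention.  Summed over all group pairs, a trait with
    H practicing groups contributes exactly C(H,2)/H to the weighted total.
    """
    arr = traits.to_numpy()
    bad = ~np.isin(arr, ("Y", "N", "U"))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid state {arr[r, c]!r} for group {traits.index[r]!r}, trait {traits.columns[c]!r}"
        )
    if len(traits) < 2:
        raise ValueError("need at least 2 groups")
    groups = list(traits.index)
    n = len(groups)
    unweighted = np.zeros((n, n))
    weighted = np.zeros((n, n))
    for t in range(arr.shape[1]):
        col = arr[:, t]
        for state in ("Y", "N"):
            members = np.flatnonzero(col == state)
            k = members.size
            if k < 2:
                continue
            ix = np.ix_(members, members)
            unweighted[ix] += 1.0
            weighted[ix] += 1.0 / k
    np.fill_diagonal(unweighted, 0.0)
    np.fill_diagonal(weighted, 0.0)
    return (
        pd.DataFrame(unweighted, index=groups, columns=groups),
        pd.DataFrame(weighted, index=groups, columns=groups),
    )


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------


def _offdiag(M: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(M.shape[0], k=1)
    return M[i, j]


def _as_matrix(M) -> np.ndarray:
    A = M.to_numpy(dtype=float) if isinstance(M, pd.DataFrame) else np.asarray(M, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("Mantel inputs must be square matrices")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("Mantel inputs must be symmetric")
    return A


def mantel(M1, M2, n_perm: int = 100_000, seed: int = 0, permutations=None):
    """Mantel test: Pearson r of off-diagonals, p from joint row/column permutations.

    One matrix's rows and columns are relabelled jointly each permutation;
    p is the proportion of permutations with r >= the observed r (ties count
    toward the null).  ``permutations`` may supply an explicit iterable of
    index permutations (then n_perm/seed are ignored).
    """
    A, B = _as_matrix(M1), _as_matrix(M2)
    if A.shape != B.shape:
        raise ValueError(f"matrix dimension mismatch: {A.shape} vs {B.shape}")
    a = _offdiag(A)
    r_obs = float(np.corrcoef(a, _offdiag(B))[0, 1])
    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = (rng.permutation(A.shape[0]) for _ in range(n_perm))
        n = n_perm
    else:
        permutations = list(permutations)
        n = len(permutations)
    exceed = 0
    for perm in permutations:
        r_p = float(np.corrcoef(a, _offdiag(B[np.ix_(perm, perm)]))[0, 1])
        exceed += r_p >= r_obs
    return r_obs, exceed / n


def partial_mantel(M1, M2, M3, n_perm: int = 100_000, seed: int = 0):
    """Partial Mantel: correlation of M1 and M2 off-diagonals given M3.

    Computed as the correlation of the residuals of each matrix's
    off-diagonals after regression on M3's (equivalently the first-order
    partial correlation); p permutes M1's labels jointly.
    """
    A, B, C = _as_matrix(M1), _as_matrix(M2), _as_matrix(M3)
    if not (A.shape == B.shape == C.shape):
        raise ValueError("matrix dimension mismatch")
    b, c = _offdiag(B), _offdiag(C)

    def partial_r(a: np.ndarray) -> float:
        ra = a - _ols_on(c, a)[2]
        rb = b - _ols_on(c, b)[2]
        return float(np.corrcoef(ra, rb)[0, 1])

    r_obs = partial_r(_offdiag(A))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(A.shape[0])
        exceed += partial_r(_offdiag(A[np.ix_(perm, perm)])) >= r_obs
    return r_obs, exceed / n_perm


# ---------------------------------------------------------------------------
# per-trait category tests
# ---------------------------------------------------------------------------


def trait_category_test(
    traits: pd.DataFrame,
    G_groups: pd.DataFrame,
    trait: str,
    category_X: str = "Y",
    category_Y: str = "U",
    n_perm: int = 10_000,
    seed: int = 0,
):
    """Do groups in category X show higher mean pairwise similarity than in Y?

    The statistic is the mean pairwise group-level genetic similarity among
    X-groups minus that among Y-groups; groups are permuted across the two
    categories.  Returns (observed, p) or None when either category has
    fewer than two groups (skipped with a logged notice).
    """
    states = traits[trait]
    gx = [g for g in states.index[states == category_X] if g in G_groups.index]
    gy = [g for g in states.index[states == category_Y] if g in G_groups.index]
    if len(gx) < 2 or len(gy) < 2:
        logger.info(
            "trait %r: categories %s/%s have %d/%d groups; test skipped",
            trait, category_X, category_Y, len(gx), len(gy),
        )
        return None
    Gm = G_groups.to_numpy(dtype=float)
    pos = {g: k for k, g in enumerate(G_groups.index)}
    ix = np.array([pos[g] for g in gx])
    iy = np.array([pos[g] for g in gy])

    def within_mean(idx: np.ndarray) -> float:
        sub = Gm[np.ix_(idx, idx)]
        return float(sub[np.triu_indices(idx.size, k=1)].mean())

    obs = within_mean(ix) - within_mean(iy)
    pool = np.concatenate([ix, iy])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        stat = within_mean(perm[: ix.size]) - within_mean(perm[ix.size :])
        exceed += stat >= obs
    return obs, exceed / n_perm


# ---------------------------------------------------------------------------
# spatial/language-adjusted similarity
# ---------------------------------------------------------------------------


def adjusted_similarity(
    sim: SimilarityMatrix,
    metadata: pd.DataFrame,
    group_branch: dict | pd.Series,
) -> pd.DataFrame:
    """Group-pair genetic similarity adjusted for spatial distance and language.

    The chain of fits -- G on d (exponential), h on d, then the G-residuals
    on the h-residuals -- is estimated using only pairs of individuals from
    *different* language branches, so the spatial corrections are not
    confounded with shared linguistic classification.  G*_ij are the final
    residuals; group-pair G* is the mean over cross-individual pairs, the
    branch-pair expectation is the mean of group-pair G* over ethnic-group
    pairs in that branch pairing, and the deviation is their difference.
    """
    group_branch = pd.Series(group_branch)
    meta = metadata.loc[[i for i in sim.ids if i in metadata.index]]
    meta = meta[meta[["lat", "lon", "elevation_m"]].notna().all(axis=1)]
    groups = meta["group"]
    branches = groups.map(group_branch)
    if branches.isna().all():
        raise ValueError("no group has a language branch assigned")
    keep = branches.notna()
    meta, groups, branches = meta[keep], groups[keep], branches[keep]
    for br in pd.unique(pd.Series(group_branch).dropna()):
        if not (branches == br).any():
            raise ValueError(f"language branch {br!r} has no sampled group")

    idx = [sim._index[i] for i in meta.index]
    G = sim.values[np.ix_(idx, idx)]
    D = pairwise_distance_km(meta["lat"].to_numpy(float), meta["lon"].to_numpy(float))
    elev = meta["elevation_m"].to_numpy(float)
    i_idx, j_idx = np.triu_indices(len(meta), k=1)
    g, d = G[i_idx, j_idx], D[i_idx, j_idx]
    h = np.abs(elev[i_idx] - elev[j_idx])
    br_arr = branches.to_numpy()
    cross = br_arr[i_idx] != br_arr[j_idx]
    if not cross.any():
        raise ValueError("no cross-branch pair available to fit the adjustment")

    fit_gd = fit_exponential(g[cross], d[cross])
    r_g = g - fit_gd.predict(d)
    eta, theta, _ = _ols_on(d[cross], h[cross])
    r_h = h - (eta + theta * d)
    a2, b2, _ = _ols_on(r_h[cross], r_g[cross])
    g_star = r_g - (a2 + b2 * r_h)

    pair_df = pd.DataFrame(
        {
            "group_a": groups.to_numpy()[i_idx],
            "group_b": groups.to_numpy()[j_idx],
            "g_star": g_star,
        }
    )
    swap = pair_df["group_a"] > pair_df["group_b"]
    pair_df.loc[swap, ["group_a", "group_b"]] = pair_df.loc[swap, ["group_b", "group_a"]].to_numpy()
    gp = (
        pair_df[pair_df["group_a"] != pair_df["group_b"]]
        .groupby(["group_a", "group_b"])["g_star"]
        .mean()
        .reset_index()
    )
    gp["branch_a"] = gp["group_a"].map(group_branch)
    gp["branch_b"] = gp["group_b"].map(group_branch)
    key = gp[["branch_a", "branch_b"]].apply(lambda r: tuple(sorted(r)), axis=1)
    gp["branch_pair"] = key
    gp["expected"] = gp.groupby("branch_pair")["g_star"].transform("mean")
    gp["deviation"] = gp["g_star"] - gp["expected"]
    return gp


# ---------------------------------------------------------------------------
# MRCA-segment intermixing
# ---------------------------------------------------------------------------


def intermix_flags(
    segments: pd.DataFrame,
    groups: dict | pd.Series,
    threshold_cM: float = 2.5,
) -> pd.DataFrame:
    """Flag group pairs with atypically long shared MRCA segments.

    ``segments`` holds per-individual-pair totals (iid1, iid2, total_cM,
    n_segments); the mean segment length per pair is total/count.  A group
    pair is flagged when at least one of its cross-individual pairings has a
    mean segment length >= the median over *all* cross-group pairings plus
    ``threshold_cM``.  Group pairs with fewer than two individual pairings
    are skipped.
    """
    groups = pd.Series(groups)
    seg = segments.copy()
    if "mean_segment" not in seg.columns:
        if (seg["n_segments"] <= 0).any():
            raise ValueError("n_segments must be positive")
        seg["mean_segment"] = seg["total_cM"] / seg["n_segments"]
    seg["group_a"] = seg["iid1"].map(groups)
    seg["group_b"] = seg["iid2"].map(groups)
    if seg[["group_a", "group_b"]].isna().any().any():
        raise ValueError("segment table contains individuals without a group label")
    cross = seg[seg["group_a"] != seg["group_b"]].copy()
    if cross.empty:
        raise ValueError("no cross-group pairings in the segment table")
    median_all = float(cross["mean_segment"].median())
    cutoff = median_all + threshold_cM
    swap = cross["group_a"] > cross["group_b"]
    cross.loc[swap, ["group_a", "group_b"]] = cross.loc[swap, ["group_b", "group_a"]].to_numpy()
    agg = cross.groupby(["group_a", "group_b"]).agg(
        n_pairings=("mean_segment", "size"),
        max_mean_segment=("mean_segment", "max"),
    )
    agg = agg[agg["n_pairings"] >= 2]
    agg["flagged"] = agg["max_mean_segment"] >= cutoff
    agg.attrs["median_all_cross"] = median_all
    agg.attrs["cutoff_cM"] = cutoff
    return agg.reset_index()


def intermix_resample_p(
    flags: pd.DataFrame,
    trait_groups: list[str],
    n_resamples: int = 10_000,
    seed: int = 0,
) -> tuple[int, float]:
    """Significance of the flagged-pair count among trait-sharing groups.

    Counts flagged pairs among the ``trait_groups``, then resamples sets of
    the same size from all groups in the flag table; p is the proportion of
    resamples with at least as many flagged pairs.
    """
    flagged_pairs = {
        frozenset((a, b))
        for a, b in flags.loc[flags["flagged"], ["group_a", "group_b"]].itertuples(index=False)
    }
    all_groups = sorted(set(flags["group_a"]) | set(flags["group_b"]))
    chosen = [g for g in trait_groups if g in all_groups]
    n = len(chosen)
    if n < 2:
        raise ValueError("need at least two trait-sharing groups present in the flag table")

    def count(subset) -> int:
        sub = list(subset)
        return sum(
            frozenset((sub[i], sub[j])) in flagged_pairs
            for i in range(len(sub))
            for j in range(i + 1, len(sub))
        )

    obs = count(chosen)
    rng = np.random.default_rng(seed)
    pool = np.array(all_groups)
    exceed = 0
    for _ in range(n_resamples):
        exceed += count(rng.choice(pool, size=n, replace=False)) >= obs
    return obs, exceed / n_resamples
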