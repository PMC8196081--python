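"""Permutation tests for exchangeable ancestry profiles between labelled groups.

The core scheme tests whether individuals from group A are more similar to
each other on average than an A individual is to a B individual, while
accounting for sample size.  Each permutation builds a mixed group C of
n_X = min(n_A, n_B) individuals -- floor(n_X/2) drawn without replacement
from each of A and B, plus (when n_X is odd) one extra not-yet-sampled
individual from A with probability 0.5, else from B -- and compares the mean
pairwise similarity within C against that among n_X individuals drawn without
replacement from Y in {A, B}.  The one-sided p value for Y is the proportion
of permutations where the within-C mean is greater than or equal to the
within-Y mean (ties count toward the null).

p values are plain proportions and may be exactly 0; pass
``add_one_correction=True`` for the (b+1)/(n+1) variant.  Every result
records its seed, permutation count and Monte-Carlo standard error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 100_000


@dataclass
class PermutationResult:
    observed: float
    n_permutations: int
    p_value: float
    seed: int
    statistic_name: str = ""
    components: dict | None = None  # e.g. the per-side p values behind a min-p summary

    @property
    def mc_se(self) -> float:
        """Monte-Carlo standard error of the estimated p value."""
        p = self.p_value
        return math.sqrt(max(p * (1.0 - p), 0.0) / self.n_permutations)


def _indices(sim: SimilarityMatrix, labels: pd.Series, value) -> np.ndarray:
    ids = labels.index[labels == value]
    return np.array([sim._index[str(i)] for i in ids], dtype=int)


def _pair_mean(vals: np.ndarray, idx: np.ndarray, eth: np.ndarray | None) -> float:
    """Mean pairwise similarity over a subset, optionally restricted to
    cross-ethnic-label pairs.  Returns nan when no eligible pair exists."""
    sub = vals[np.ix_(idx, idx)]
    mask = ~np.eye(idx.size, dtype=bool)
    if eth is not None:
        e = eth[idx]
        mask &= e[:, None] != e[None, :]
    if not mask.any():
        return float("nan")
    return float(sub[mask].mean())


def _cross_mean(vals: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> float:
    return float(vals[np.ix_(ia, ib)].mean())


def _sample_mixed_group(rng: np.random.Generator, ia: np.ndarray, ib: np.ndarray, n_x: int) -> np.ndarray:
    half = n_x // 2
    pick_a = rng.choice(ia, size=half, replace=False)
    pick_b = rng.choice(ib, size=half, replace=False)
    picks = [pick_a, pick_b]
    if n_x % 2:
        # the extra member comes from the not-yet-sampled individuals
        if rng.random() < 0.5:
            pool = np.setdiff1d(ia, pick_a, assume_unique=True)
        else:
            pool = np.setdiff1d(ib, pick_b, assume_unique=True)
        picks.append(rng.choice(pool, size=1))
    return np.concatenate(picks)


def _exchangeability_core(
    vals: np.ndarray,
    ia: np.ndarray,
    ib: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    eth: np.ndarray | None = None,
    restrict_a: bool = False,
    restrict_b: bool = False,
) -> tuple[float, float]:
    """Shared engine: returns (p_A, p_B).

    ``restrict_a``/``restrict_b`` apply the cross-ethnic-label restriction to
    the averages in the test of Y=A / Y=B respectively (the mixed group C is
    restricted in the same test where Y is).
    """
    n_x = min(ia.size, ib.size)
    if n_x < 2:
        raise ValueError("smaller group needs >=2 individuals")
    exceed_a = exceed_b = 0
    for _ in range(n_perm):
        ic = _sample_mixed_group(rng, ia, ib, n_x)
        ya = rng.choice(ia, size=n_x, replace=False)
        yb = rng.choice(ib, size=n_x, replace=False)
        for restrict, iy, which in ((restrict_a, ya, "a"), (restrict_b, yb, "b")):
            e = eth if restrict else None
            mc = _pair_mean(vals, ic, e)
            my = _pair_mean(vals, iy, e)
            # a draw with no eligible pair is treated as a tie (toward the null)
            hit = math.isnan(mc) or math.isnan(my) or mc >= my
            if which == "a":
                exceed_a += hit
            else:
                exceed_b += hit
    return exceed_a / n_perm, exceed_b / n_perm


def group_pair_test(
    sim: SimilarityMatrix,
    labels: pd.Series | dict,
    A: str,
    B: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    add_one_correction: bool = False,
) -> tuple[PermutationResult, PermutationResult]:
    """Test exchangeability of ancestry profiles between groups A and B.

    Returns (result for Y=A, result for Y=B); small p for Y means individuals
    from Y are more similar to each other than to the other group's members.
    """
    labels = pd.Series(labels)
    vals = sim.values
    ia, ib = _indices(sim, labels, A), _indices(sim, labels, B)
    rng = np.random.default_rng(seed)
    p_a, p_b = _exchangeability_core(vals, ia, ib, n_perm, rng)
    if add_one_correction:
        p_a = (p_a * n_perm + 1) / (n_perm + 1)
        p_b = (p_b * n_perm + 1) / (n_perm + 1)
    obs_a = _pair_mean(vals, ia, None) - _cross_mean(vals, ia, ib)
    obs_b = _pair_mean(vals, ib, None) - _cross_mean(vals, ia, ib)
    return (
        PermutationResult(obs_a, n_perm, p_a, seed, f"within-{A} minus cross excess"),
        PermutationResult(obs_b, n_perm, p_b, seed, f"within-{B} minus cross excess"),
    )


def language_class_test(
    sim: SimilarityMatrix,
    class_labels: pd.Series | dict,
    ethnic_labels: pd.Series | dict,
    class_A: str,
    class_B: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> PermutationResult:
    """Exchangeability of two language classifications, min over both tests.

    Whenever a classification spans more than two ethnic/occupation labels,
    the averages in its test (including the mixed group C) use only pairs from
    different ethnic labels, so that strong within-ethnicity similarity does
    not masquerade as within-classification similarity.  The reported p is
    min(p_A, p_B); the min of two dependent p values is anti-conservative as a
    test in itself, so the per-side values are kept in ``components``.
    """
    class_labels = pd.Series(class_labels)
    eth_series = pd.Series(ethnic_labels)
    vals = sim.values
    ia = _indices(sim, class_labels, class_A)
    ib = _indices(sim, class_labels, class_B)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both classifications need at least one ethnic label with members")
    eth = np.empty(len(sim.ids), dtype=object)
    for i, iid in enumerate(sim.ids):
        eth[i] = eth_series.get(iid)
    n_labels_a = len(set(eth[ia]))
    n_labels_b = len(set(eth[ib]))
    restrict_a = n_labels_a > 2
    restrict_b = n_labels_b > 2
    for restrict, idx, name in ((restrict_a, ia, class_A), (restrict_b, ib, class_B)):
        if restrict and math.isnan(_pair_mean(vals, idx, eth)):
            raise ValueError(f"no eligible cross-label pair within classification {name!r}")
    rng = np.random.default_rng(seed)
    p_a, p_b = _exchangeability_core(
        vals, ia, ib, n_perm, rng, eth=eth, restrict_a=restrict_a, restrict_b=restrict_b
    )
    obs = _pair_mean(vals, ia, eth if restrict_a else None) - _cross_mean(vals, ia, ib)
    return PermutationResult(
        obs, n_perm, min(p_a, p_b), seed, f"min-p({class_A},{class_B})",
        components={"p_" + class_A: p_a, "p_" + class_B: p_b},
    )


def amax_competition_test(
    sim: SimilarityMatrix,
    labels: pd.Series | dict,
    A: str,
    A_max: str,
    B: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> PermutationResult:
    """Is A_max significantly more similar to A than group B is?

    Permutes individuals of A_max and B into pseudo-groups of the original
    sizes; the statistic is mean sim(A, pseudo-A_max) - mean sim(A, pseudo-B)
    and p is the proportion of permutations with statistic >= the observed
    difference.
    """
    if len({A, A_max, B}) != 3:
        raise ValueError("A, A_max and B must be three distinct groups")
    labels = pd.Series(labels)
    vals = sim.values
    ia = _indices(sim, labels, A)
    im = _indices(sim, labels, A_max)
    ib = _indices(sim, labels, B)
    if np.intersect1d(im, ib).size or np.intersect1d(ia, im).size or np.intersect1d(ia, ib).size:
        raise ValueError("groups overlap")
    obs = _cross_mean(vals, ia, im) - _cross_mean(vals, ia, ib)
    pool = np.concatenate([im, ib])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        stat = _cross_mean(vals, ia, perm[: im.size]) - _cross_mean(vals, ia, perm[im.size :])
        exceed += stat >= obs
    return PermutationResult(obs, n_perm, exceed / n_perm, seed, f"sim({A},{A_max})-sim({A},{B})")


def religion_within_group_test(
    sim: SimilarityMatrix,
    group_labels: pd.Series | dict,
    religion_labels: pd.Series | dict,
    group: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    min_total: int = 5,
) -> dict[tuple[str, str], tuple[PermutationResult, PermutationResult]] | None:
    """Exchangeability between religion-defined subgroups within one group.

    Requires at least ``min_total`` individuals spread over >=2 religion
    categories (each tested pair of categories needs >=2 members per side);
    otherwise the test is skipped with a logged notice and None is returned.
    """
    group_labels = pd.Series(group_labels)
    religion_labels = pd.Series(religion_labels)
    members = group_labels.index[group_labels == group]
    rel = religion_labels.reindex(members).dropna()
    counts = rel.value_counts()
    eligible = sorted(counts.index[counts >= 2])
    if len(rel) < min_total or len(eligible) < 2:
        logger.info(
            "religion test skipped for group %r: %d individuals in %d usable categories",
            group, len(rel), len(eligible),
        )
        return None
    results = {}
    for i, r1 in enumerate(eligible):
        for r2 in eligible[i + 1 :]:
            sub = rel[rel.isin([r1, r2])]
            res = group_pair_test(sim, sub, r1, r2, n_perm=n_perm, seed=seed)
            results[(r1, r2)] = res
    return results
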