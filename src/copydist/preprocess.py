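"""Relatedness pruning and within-group diversity summaries.

Related pairs are flagged from a PLINK-style PI_HAT table using per-population
outlier thresholds rather than a single fixed cutoff, so that populations with
low background diversity (hence inflated baseline PI_HAT) are not over-pruned.
A pair (i in pop_i, k in pop_k) is flagged iff

    PI_HAT > 0.15  and  PI_HAT > min( X_i + 3*max(0.02, S_i),
                                      Y_i + 3*max(0.02, D_i),
                                      X_k + 3*max(0.02, S_k),
                                      Y_k + 3*max(0.02, D_k) )

where X/Y/S/D are the mean/median/standard deviation/median absolute
deviation of within-population PI_HAT values.  Populations with <= 2 sampled
individuals have undefined (or degenerate-zero) spread statistics; any pair
with PI_HAT > 0.15 containing one of their members is flagged directly.
Flagged individuals are then removed greedily, most-paired first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PIHAT_FLOOR = 0.15
SPREAD_FLOOR = 0.02


@dataclass
class PopPihatStats:
    """Within-population PI_HAT summary: mean X, median Y, SD S, MAD D."""

    population: str
    n_individuals: int
    mean: float
    median: float
    sd: float
    mad: float
    small: bool  # <=2 sampled individuals: spread undefined, small-pop clause applies

    @property
    def threshold(self) -> float:
        if self.small:
            return PIHAT_FLOOR
        return min(
            self.mean + 3.0 * max(SPREAD_FLOOR, self.sd),
            self.median + 3.0 * max(SPREAD_FLOOR, self.mad),
        )


def population_pihat_stats(pihat: pd.DataFrame, pops: dict | pd.Series) -> dict[str, PopPihatStats]:
    """Per-population PI_HAT statistics from the full pair table.

    ``pops`` maps every individual id to its population label.  Statistics use
    the sample standard deviation (n-1 denominator) and the unscaled MAD.
    """
    pops = dict(pd.Series(pops))
    ids = set(pihat["iid1"]) | set(pihat["iid2"])
    missing = [i for i in ids if i not in pops]
    if missing:
        raise ValueError(f"individual {missing[0]!r} has no population label")
    sizes = pd.Series(pops).value_counts()
    within = pihat[
        (pihat["iid1"].map(pops) == pihat["iid2"].map(pops))
    ].assign(pop=lambda d: d["iid1"].map(pops))
    out: dict[str, PopPihatStats] = {}
    for pop in sorted(set(pops.values())):
        n = int(sizes.get(pop, 0))
        vals = within.loc[within["pop"] == pop, "pi_hat"].to_numpy()
        small = n <= 2
        if small or vals.size < 2:
            out[pop] = PopPihatStats(pop, n, float("nan"), float("nan"), float("nan"), float("nan"), True)
        else:
            out[pop] = PopPihatStats(
                pop,
                n,
                float(np.mean(vals)),
                float(np.median(vals)),
                float(np.std(vals, ddof=1)),
                float(np.median(np.abs(vals - np.median(vals)))),
                False,
            )
    return out


def flag_related_pairs(pihat: pd.DataFrame, pops: dict | pd.Series) -> pd.DataFrame:
    """Flag putatively related pairs by the per-population outlier rule.

    Returns the flagged subset of the PI_HAT table (with pop columns).
    """
    pops = dict(pd.Series(pops))
    stats_by_pop = population_pihat_stats(pihat, pops)
    p1 = pihat["iid1"].map(pops)
    p2 = pihat["iid2"].map(pops)
    thr = np.minimum(
        p1.map(lambda p: stats_by_pop[p].threshold).to_numpy(),
        p2.map(lambda p: stats_by_pop[p].threshold).to_numpy(),
    )
    pv = pihat["pi_hat"].to_numpy()
    flagged = (pv > PIHAT_FLOOR) & (pv > thr)
    out = pihat.loc[flagged].copy()
    out["pop1"] = p1[flagged]
    out["pop2"] = p2[flagged]
    return out.reset_index(drop=True)


def greedy_prune(flagged: pd.DataFrame | list[tuple[str, str]]) -> list[str]:
    """Greedy vertex cover of the flagged-pair graph.

    Repeatedly removes the individual appearing in the most remaining pairs
    (ties broken by lexicographically smallest id) until no pair survives.
    Returns the removed ids in removal order.
    """
    if isinstance(flagged, pd.DataFrame):
        pairs = list(zip(flagged["iid1"], flagged["iid2"]))
    else:
        pairs = list(flagged)
    pairs = [(str(a), str(b)) for a, b in pairs]
    removed: list[str] = []
    while pairs:
        counts: dict[str, int] = {}
        for a, b in pairs:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        top = max(counts.values())
        victim = min(i for i, c in counts.items() if c == top)
        removed.append(victim)
        pairs = [(a, b) for a, b in pairs if victim not in (a, b)]
    return removed


def prune_report(pihat: pd.DataFrame, pops: dict | pd.Series) -> dict:
    """Flag, prune, and audit: removed ids plus per-population statistics.

    After pruning, any surviving pair with PI_HAT >= 0.2 triggers a logged
    warning (a soft check: study-like cohorts end below 0.2, but the rule does
    not guarantee it).
    """
    flagged = flag_related_pairs(pihat, pops)
    removed = greedy_prune(flagged)
    gone = set(removed)
    surviving = pihat[~(pihat["iid1"].isin(gone) | pihat["iid2"].isin(gone))]
    high = surviving[surviving["pi_hat"] >= 0.2]
    if len(high):
        logger.warning("%d surviving pairs have PI_HAT >= 0.2 after pruning", len(high))
    return {
        "n_flagged_pairs": int(len(flagged)),
        "removed": removed,
        "n_removed": len(removed),
        "n_surviving_pairs_ge_0.2": int(len(high)),
        "population_stats": {
            p: vars(s) for p, s in population_pihat_stats(pihat, pops).items()
        },
    }


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def homozygosity_by_group(genotypes: pd.DataFrame, groups: dict | pd.Series) -> pd.Series:
    """Median per-group count of homozygous genotypes (0 or 2) per individual.

    ``genotypes`` is individuals x sites with values in {0, 1, 2} and NaN for
    missing calls; missing sites do not count.
    """
    groups = pd.Series(groups)
    counts = genotypes.isin([0, 2]).sum(axis=1)
    glabels = groups.reindex(genotypes.index)
    if glabels.isna().any():
        raise ValueError(f"individual {glabels.index[glabels.isna()][0]!r} has no group label")
    med = counts.groupby(glabels).median()
    empty = set(groups.unique()) - set(med.index)
    if empty:
        raise ValueError(f"group {sorted(empty)[0]!r} has no genotyped individuals")
    return med


def diversity_vs_census(diversity: pd.Series, census: pd.Series):
    """OLS of a per-group diversity measure on census population size.

    Returns (slope, two-sided p).  A negative slope with small p mirrors the
    decline of homozygosity with increasing census size.
    """
    div, cen = diversity.align(census, join="inner")
    if len(div) < 3:
        raise ValueError("need at least 3 groups")
    if np.ptp(cen.to_numpy(dtype=float)) == 0:
        raise ValueError("census sizes are constant")
    res = stats.linregress(cen.to_numpy(dtype=float), div.to_numpy(dtype=float))
    return float(res.slope), float(res.pvalue)
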