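"""TVD-based genetic similarity from copying profiles.

Genetic similarity between individuals i and j is 1 - TVD_ij, where

    TVD_ij = 0.5 * sum_k | f_k^i - f_k^j |

and f_k is the proportion of genome-wide DNA that an individual matches to
donor group k.  Between-group similarity is the mean of the pairwise values
over all cross-individual pairings (the pairwise-mean convention), not the
TVD of the group-mean profiles; the two differ in general and the pipeline
uses the former throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


def tvd(f_a: np.ndarray, f_b: np.ndarray) -> float:
    """Total variation distance between two normalized copying profiles."""
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    if f_a.shape != f_b.shape:
        raise ValueError(f"profile length mismatch: {f_a.shape} vs {f_b.shape}")
    return 0.5 * float(np.abs(f_a - f_b).sum())


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise 1-TVD values with a panel tag.

    The diagonal is defined as 1 (an individual is identical to itself).
    """

    ids: list[str]
    values: np.ndarray
    panel: str = "internal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix is not symmetric")
        if np.any((self.values < -1e-12) | (self.values > 1 + 1e-12)):
            raise ValueError("similarity values outside [0, 1]")
        np.fill_diagonal(self.values, 1.0)
        self._index = {v: k for k, v in enumerate(self.ids)}

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def condensed(self) -> np.ndarray:
        """Off-diagonal upper-triangle values in scipy condensed order."""
        return squareform(self.values - np.eye(len(self.ids)), checks=False)


def similarity_matrix(profiles: pd.DataFrame, panel: str | None = None) -> SimilarityMatrix:
    """Pairwise 1-TVD for a recipients x donor-groups frame of proportions.

    Rows must already be normalized (proportions summing to 1).
    """
    X = profiles.to_numpy(dtype=float)
    totals = X.sum(axis=1)
    if not np.allclose(totals, 1.0, atol=1e-6):
        raise ValueError("profiles are not normalized; call io.normalize_rows first")
    d = 0.5 * pdist(X, metric="cityblock")
    sim = 1.0 - squareform(d)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(
        ids=list(map(str, profiles.index)),
        values=np.clip(sim, 0.0, 1.0),
        panel=panel or profiles.attrs.get("panel", "internal"),
    )


def group_similarity(
    sim: SimilarityMatrix,
    labels: pd.Series | dict,
    A: str,
    B: str,
    cross_only: bool = False,
    cross_labels: pd.Series | dict | None = None,
) -> float:
    """Mean pairwise 1-TVD over all (i in A, j in B) pairs, i != j.

    With ``cross_only``, pairs whose members share the finer ethnic/occupation
    label in ``cross_labels`` are excluded (used when A and B are language
    classifications spanning several ethnic groups).
    """
    labels = pd.Series(labels)
    ia = np.array([sim._index[i] for i in labels.index[labels == A]])
    ib = np.array([sim._index[i] for i in labels.index[labels == B]])
    if ia.size == 0 or ib.size == 0:
        raise ValueError(f"empty group: {A!r} has {ia.size}, {B!r} has {ib.size} members")
    if A == B and ia.size < 2:
        raise ValueError(f"group {A!r} needs >=2 members for within-group similarity")
    vals = sim.values[np.ix_(ia, ib)]
    mask = np.ones(vals.shape, dtype=bool)
    if A == B:
        mask &= ~np.eye(ia.size, dtype=bool)
    if cross_only:
        if cross_labels is None:
            raise ValueError("cross_only requires cross_labels")
        cl = pd.Series(cross_labels)
        la = cl.reindex(labels.index[labels == A]).to_numpy()
        lb = cl.reindex(labels.index[labels == B]).to_numpy()
        mask &= la[:, None] != lb[None, :]
    if not mask.any():
        raise ValueError(f"no eligible pair between {A!r} and {B!r}")
    return float(vals[mask].mean())


def closest_group(sim: SimilarityMatrix, labels: pd.Series | dict, A: str):
    """The group A_max with highest mean pairwise similarity to A, plus ranking.

    Ties are broken lexicographically on group name (deterministic).
    Returns (A_max, ranked DataFrame with columns group, similarity).
    """
    labels = pd.Series(labels)
    others = sorted(set(labels) - {A})
    if not others:
        raise ValueError("need at least two groups")
    rows = [(B, group_similarity(sim, labels, A, B)) for B in others]
    ranked = pd.DataFrame(rows, columns=["group", "similarity"]).sort_values(
        ["similarity", "group"], ascending=[False, True], kind="mergesort"
    )
    return str(ranked.iloc[0]["group"]), ranked.reset_index(drop=True)


def mean_mrca_segment(total_cM: float, n_chunks: float) -> float:
    """Mean MRCA segment length: total matched cM divided by segment count."""
    if n_chunks <= 0:
        raise ValueError(f"n_chunks must be positive, got {n_chunks}")
    return float(total_cM) / float(n_chunks)


def compare_panels(
    sim_internal: SimilarityMatrix,
    sim_external: SimilarityMatrix,
    labels: pd.Series | dict,
) -> tuple[pd.DataFrame, float]:
    """Align per-group-pair mean similarities under both panels.

    Returns a long table (group_a, group_b, internal, external) over all
    unordered group pairs (including within-group) and the Pearson correlation
    of the two matrices' off-diagonal individual-level entries.
    """
    if sim_internal.ids != sim_external.ids:
        raise ValueError("panels cover different individuals")
    labels = pd.Series(labels)
    groups = sorted(set(labels))
    counts = labels.value_counts()
    rows = []
    for a_i, A in enumerate(groups):
        for B in groups[a_i:]:
            if A == B and counts[A] < 2:
                continue
            rows.append(
                dict(
                    group_a=A,
                    group_b=B,
                    internal=group_similarity(sim_internal, labels, A, B),
                    external=group_similarity(sim_external, labels, A, B),
                )
            )
    off_i = sim_internal.condensed()
    off_e = sim_external.condensed()
    r = float(np.corrcoef(off_i, off_e)[0, 1])
    return pd.DataFrame(rows), r


def equalize_panel(profiles: pd.DataFrame, donor_sizes: pd.Series | dict) -> pd.DataFrame:
    """Down-weight donor columns to emulate painting against equal donor counts.

    Each column is divided by its donor-group sample size and rows are
    re-normalised; this approximates the leave-one-out repainting consistency
    check without re-running the painting model.
    """
    sizes = pd.Series(donor_sizes).reindex(profiles.columns)
    if sizes.isna().any():
        raise ValueError(f"missing donor size for {sizes.index[sizes.isna()][0]!r}")
    if (sizes <= 0).any():
        raise ValueError("donor sizes must be positive")
    out = profiles / sizes.to_numpy()[None, :]
    out = out.div(out.sum(axis=1), axis=0)
    out.attrs.update(profiles.attrs)
    return out
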