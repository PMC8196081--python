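"""Domain types, tabular readers/writers and elementary geometry.

File dialects
-------------
Copying matrices follow the CHROMOPAINTER ``.chunkcounts.out`` /
``.chunklengths.out`` layout: a headered whitespace-separated table whose
first row holds donor-group names and whose first column holds the recipient
individual id.  Metadata is a TSV with the mandatory header
``id group lat lon elevation_m language_group first_language second_language
religion``; missing fields are empty cells (explicit nulls).  Trait tables are
CSV with groups as rows, traits as columns and cells in {Y, N, U}.  PI_HAT
tables are whitespace tables with at least ``IID1 IID2 PI_HAT`` columns plus a
two-column population map.  Admixture summaries are TSV with one row per
(cluster, source).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
"""Mean Earth radius used by the haversine distance (spherical model)."""

METADATA_COLUMNS = [
    "id",
    "group",
    "lat",
    "lon",
    "elevation_m",
    "language_group",
    "first_language",
    "second_language",
    "religion",
]

PANELS = ("internal", "external")


class ParseError(ValueError):
    """A malformed table cell or row, with its location in the message."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CopyingProfile:
    """One individual's donor-group matching vector under a named panel.

    ``values`` are non-negative genome-wide expected chunk counts or total
    chunk lengths; ``normalized`` are the proportions f_k of genome-wide DNA
    matched to each donor group (summing to 1).
    """

    individual_id: str
    panel: str
    donor_groups: list[str]
    values: np.ndarray
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.panel not in PANELS:
            raise ValueError(f"panel must be one of {PANELS}, got {self.panel!r}")
        self.values = np.asarray(self.values, dtype=float)
        if len(self.donor_groups) != self.values.size:
            raise ValueError(
                f"profile {self.individual_id!r}: {len(self.donor_groups)} donor "
                f"names but {self.values.size} values"
            )
        if len(set(self.donor_groups)) != len(self.donor_groups):
            raise ValueError(f"profile {self.individual_id!r}: duplicate donor-group names")
        if np.any(self.values < 0):
            k = int(np.argmax(self.values < 0))
            raise ValueError(
                f"profile {self.individual_id!r}: negative value in donor column "
                f"{self.donor_groups[k]!r}"
            )
        total = float(self.values.sum())
        if total <= 0:
            raise ValueError(f"profile {self.individual_id!r}: all values are zero")
        if self.individual_id in self.donor_groups:
            k = self.donor_groups.index(self.individual_id)
            if self.values[k] != 0:
                raise ValueError(
                    f"profile {self.individual_id!r}: nonzero self-matching entry "
                    "(self-copying is forbidden)"
                )
        self.normalized = self.values / total
        assert abs(self.normalized.sum() - 1.0) < 1e-9


@dataclass
class AdmixtureSource:
    surrogate: str
    proportion: float
    role: str  # "major" or "minority"


@dataclass
class AdmixtureSummary:
    """Per-cluster admixture record: source surrogates, date and CI in generations."""

    cluster_id: str
    sources: list[AdmixtureSource]
    date_generations: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        total = sum(s.proportion for s in self.sources)
        if any(s.proportion < 0 for s in self.sources):
            raise ValueError(f"cluster {self.cluster_id!r}: negative source proportion")
        if total > 1 + 1e-6:
            raise ValueError(
                f"cluster {self.cluster_id!r}: source proportions sum to {total:.6f} > 1"
            )
        if not (self.ci_low <= self.date_generations <= self.ci_high):
            raise ValueError(
                f"cluster {self.cluster_id!r}: date {self.date_generations} outside "
                f"CI [{self.ci_low}, {self.ci_high}]"
            )

    @property
    def minority_surrogate(self) -> str:
        minor = [s for s in self.sources if s.role == "minority"]
        if not minor:
            raise ValueError(f"cluster {self.cluster_id!r}: no minority source recorded")
        return minor[0].surrogate


# ---------------------------------------------------------------------------
# copying matrices
# ---------------------------------------------------------------------------


def read_copying_matrix(path, panel: str) -> list[CopyingProfile]:
    """Read a chunkcounts/chunklengths-style table into copying profiles.

    The first row holds donor-group names, the first column recipient ids.
    Raises :class:`ParseError` for non-numeric cells (naming row and column)
    and for duplicate recipient ids; profile invariants (non-negativity,
    self-copying) are enforced by :class:`CopyingProfile`.
    """
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise ParseError(f"{path}: empty file")
        donors = header[1:] if header[0].lower() in {"recipient", "id", "ind"} else header
        rows: list[tuple[str, np.ndarray]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            rid, cells = fields[0], fields[1:]
            if rid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate recipient id {rid!r}")
            seen.add(rid)
            if len(cells) != len(donors):
                raise ParseError(
                    f"{path}:{lineno}: row {rid!r} has {len(cells)} values, "
                    f"expected {len(donors)}"
                )
            vals = np.empty(len(cells))
            for k, cell in enumerate(cells):
                try:
                    vals[k] = float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in row {rid!r}, "
                        f"column {donors[k]!r}"
                    ) from None
            rows.append((rid, vals))
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return [CopyingProfile(rid, panel, list(donors), vals) for rid, vals in rows]


def write_copying_matrix(path, profiles: Sequence[CopyingProfile] | pd.DataFrame) -> None:
    """Write profiles (or a recipients x donors frame) in the chunkcounts dialect."""
    df = profiles if isinstance(profiles, pd.DataFrame) else profiles_to_frame(profiles, normalized=False)
    with open(path, "w") as fh:
        fh.write("Recipient " + " ".join(map(str, df.columns)) + "\n")
        for rid, row in df.iterrows():
            fh.write(str(rid) + " " + " ".join(repr(float(v)) for v in row.to_numpy()) + "\n")


def profiles_to_frame(profiles: Sequence[CopyingProfile], normalized: bool = True) -> pd.DataFrame:
    """Stack profiles into a recipients x donor-groups DataFrame.

    All profiles must share one panel and one donor-group ordering.
    """
    if not profiles:
        raise ValueError("no profiles given")
    donors = profiles[0].donor_groups
    panel = profiles[0].panel
    for p in profiles:
        if p.donor_groups != donors:
            raise ValueError(f"profile {p.individual_id!r}: donor-group mismatch")
        if p.panel != panel:
            raise ValueError(f"profile {p.individual_id!r}: panel mismatch")
    data = np.vstack([(p.normalized if normalized else p.values) for p in profiles])
    df = pd.DataFrame(data, index=[p.individual_id for p in profiles], columns=donors)
    df.attrs["panel"] = panel
    df.attrs["normalized"] = normalized
    return df


def normalize_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise a copying matrix to proportions f_k summing to 1."""
    totals = df.to_numpy().sum(axis=1)
    if np.any(totals <= 0):
        bad = df.index[totals <= 0][0]
        raise ValueError(f"row {bad!r} has non-positive total")
    out = df.div(totals, axis=0)
    out.attrs.update(df.attrs)
    out.attrs["normalized"] = True
    return out


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------


def read_metadata(path) -> pd.DataFrame:
    """Read the per-individual metadata TSV.

    Missing fields (e.g. no recorded birthplace) are explicit nulls; analyses
    that require a field exclude and count pairs with nulls themselves.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "group": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing metadata columns {missing}")
    df = df[METADATA_COLUMNS]
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ParseError(f"{path}: duplicate individual id {dup!r}")
    for col, lo, hi in [("lat", -90.0, 90.0), ("lon", -180.0, 180.0)]:
        vals = df[col]
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        if bad.any():
            rid = df.loc[bad, "id"].iloc[0]
            raise ParseError(f"{path}: {col} out of range for individual {rid!r}")
    ev = df["elevation_m"]
    if np.isinf(ev.fillna(0.0)).any():
        rid = df.loc[np.isinf(ev.fillna(0.0)), "id"].iloc[0]
        raise ParseError(f"{path}: non-finite elevation for individual {rid!r}")
    return df.set_index("id", drop=False)


def write_metadata(path, df: pd.DataFrame) -> None:
    df.reset_index(drop=True)[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

TRAIT_STATES = ("Y", "N", "U")


def read_traits(path) -> pd.DataFrame:
    """Read the group x cultural-trait CSV (cells Y/N/U, groups as rows)."""
    df = pd.read_csv(path, index_col=0, dtype=str)
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicate group {df.index[df.index.duplicated()][0]!r}")
    if df.columns.duplicated().any():
        raise ParseError(f"{path}: duplicate trait {df.columns[df.columns.duplicated()][0]!r}")
    arr = df.to_numpy()
    bad = ~np.isin(arr, TRAIT_STATES)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: invalid state {arr[r, c]!r} for group {df.index[r]!r}, "
            f"trait {df.columns[c]!r} (expected Y/N/U)"
        )
    return df


def write_traits(path, df: pd.DataFrame) -> None:
    df.to_csv(path)


# ---------------------------------------------------------------------------
# PI_HAT tables
# ---------------------------------------------------------------------------


def read_pihat(path, popmap) -> pd.DataFrame:
    """Read a PLINK ``.genome``-style PI_HAT table plus a population map.

    ``popmap`` is a path to a two-column TSV (id, population) or a mapping.
    Returns a frame with columns iid1, iid2, pi_hat, pop1, pop2.
    """
    df = pd.read_csv(path, sep=r"\s+")
    cols = {c.upper(): c for c in df.columns}
    for need in ("IID1", "IID2", "PI_HAT"):
        if need not in cols:
            raise ParseError(f"{path}: missing column {need}")
    out = pd.DataFrame(
        {
            "iid1": df[cols["IID1"]].astype(str),
            "iid2": df[cols["IID2"]].astype(str),
            "pi_hat": pd.to_numeric(df[cols["PI_HAT"]], errors="coerce"),
        }
    )
    if out["pi_hat"].isna().any():
        row = int(np.argmax(out["pi_hat"].isna().to_numpy()))
        raise ParseError(f"{path}: non-numeric PI_HAT in data row {row + 1}")
    if ((out["pi_hat"] < 0) | (out["pi_hat"] > 1)).any():
        raise ParseError(f"{path}: PI_HAT outside [0, 1]")
    if (out["iid1"] == out["iid2"]).any():
        rid = out.loc[out["iid1"] == out["iid2"], "iid1"].iloc[0]
        raise ParseError(f"{path}: self-pair for individual {rid!r}")
    if not isinstance(popmap, dict):
        pm = pd.read_csv(popmap, sep="\t", dtype=str)
        popmap = dict(zip(pm.iloc[:, 0], pm.iloc[:, 1]))
    for side in ("iid1", "iid2"):
        unknown = ~out[side].isin(popmap)
        if unknown.any():
            raise ParseError(f"{path}: individual {out.loc[unknown, side].iloc[0]!r} missing from population map")
    out["pop1"] = out["iid1"].map(popmap)
    out["pop2"] = out["iid2"].map(popmap)
    return out


def write_pihat(path, df: pd.DataFrame, popmap_path=None) -> None:
    df[["iid1", "iid2", "pi_hat"]].rename(
        columns={"iid1": "IID1", "iid2": "IID2", "pi_hat": "PI_HAT"}
    ).to_csv(path, sep=" ", index=False)
    if popmap_path is not None:
        pm = pd.concat(
            [
                df[["iid1", "pop1"]].rename(columns={"iid1": "id", "pop1": "population"}),
                df[["iid2", "pop2"]].rename(columns={"iid2": "id", "pop2": "population"}),
            ]
        ).drop_duplicates("id")
        pm.to_csv(popmap_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# admixture summaries
# ---------------------------------------------------------------------------


def read_admixture_summaries(path) -> list[AdmixtureSummary]:
    """Read the one-row-per-(cluster, source) admixture summary TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"cluster": str, "surrogate": str, "role": str})
    need = {"cluster", "surrogate", "proportion", "role", "date_generations", "ci_low", "ci_high"}
    missing = need - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for cid, sub in df.groupby("cluster", sort=False):
        dates = sub[["date_generations", "ci_low", "ci_high"]].drop_duplicates()
        if len(dates) != 1:
            raise ParseError(f"{path}: inconsistent dates for cluster {cid!r}")
        sources = [
            AdmixtureSource(r.surrogate, float(r.proportion), r.role)
            for r in sub.itertuples()
        ]
        d = dates.iloc[0]
        out.append(
            AdmixtureSummary(cid, sources, float(d.date_generations), float(d.ci_low), float(d.ci_high))
        )
    return out


def write_admixture_summaries(path, summaries: Iterable[AdmixtureSummary]) -> None:
    rows = []
    for s in summaries:
        for src in s.sources:
            rows.append(
                dict(
                    cluster=s.cluster_id,
                    surrogate=src.surrogate,
                    proportion=src.proportion,
                    role=src.role,
                    date_generations=s.date_generations,
                    ci_low=s.ci_low,
                    ci_high=s.ci_high,
                )
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km on a sphere of radius 6371.0 km.

    Accepts scalars or arrays (degrees).  Raises for out-of-range coordinates.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180):
            raise ValueError("longitude outside [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    out = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def elevation_diff_m(e1, e2):
    """Absolute elevation difference in meters; order-invariant."""
    e1, e2 = np.asarray(e1, dtype=float), np.asarray(e2, dtype=float)
    if np.any(~np.isfinite(e1)) or np.any(~np.isfinite(e2)):
        raise ValueError("elevations must be finite")
    out = np.abs(e1 - e2)
    return float(out) if out.ndim == 0 else out


def pairwise_distance_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Full n x n haversine matrix for vectors of coordinates."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    return haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
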