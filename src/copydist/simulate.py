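"""Synthetic cohorts with the statistical structure the analyses assume.

The generator emulates the features of a painted Ethiopian-style cohort that
the downstream statistics consume, without any sequence-level simulation:

* copying vectors whose between-individual similarity declines exponentially
  with geographic distance (and linearly with elevation difference),
* endogamy -- inflated self-group copying visible only in the internal panel,
* elevated similarity and long shared MRCA segments among groups connected
  by recent admixture or shared cultural practices,
* planted close relatives in the PI_HAT table.

Construction.  Donor groups are an explicit feature basis: one shared pool
donor, one self donor per group, and one overlap donor per unordered group
pair.  Group g's center puts mass alpha on the pool, m_ab on the overlap
donor of each pair (a,b), and the remainder on its self donor.  Because
1 - TVD(f, f') equals the total shared mass for profiles on this basis, the
expected similarity between groups a and b is exactly

    alpha + beta * exp(-lambda * d_ab) + max(0, a_h + delta_h * h_ab) [+ boosts]

Individual variation has two parts.  Each individual owns a private donor
(its close kin) carrying mass zeta_i ~ |N(0, sigma_z^2)| taken from the
group self donor, so within-group similarity is 1 - max(zeta_i, zeta_j)
(~0.90 at the default sigma_z) while cross-group similarity is untouched.
A second, small noise eta_i ~ N(0, s^2) shifts mass between pool and self
donors, perturbing every cross-group similarity by min(eta_i, eta_j) -- a
term with constant mean and SD ~0.02 at the default s -- so the planted
decay survives in expectation.  Endogamy moves center mass from pool to
self in the internal panel only; admixture edges mix group centers linearly
in both panels; trait cliques and religion splits add extra shared donors
to the internal panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .io import haversine_km, pairwise_distance_km

LANGUAGE_CLASSES = ["AA-Cushitic", "AA-Omotic", "AA-Semitic", "NS"]
RELIGIONS = ["Christian", "Muslim", "Jewish", "Traditional"]
RELIGION_PROBS = [0.5, 0.3, 0.1, 0.1]


@dataclass
class AdmixtureEdge:
    """Recent gene flow from ``source`` into ``target``."""

    target: str
    source: str
    fraction: float
    generations: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"mixing fraction must be in [0, 1], got {self.fraction}")
        if self.generations <= 0:
            raise ValueError("admixture date must be positive generations ago")


@dataclass
class ScenarioConfig:
    """Study conditions for a synthetic cohort.

    Spatial parameters follow the between-group decay actually planted:
    similarity alpha_shared + beta_geo*exp(-lambda_geo*d) between group
    centers, plus an elevation term alpha_elev + delta_elev*h that reaches
    zero at 2500 m.  ``self_noise_sd`` sets the individual private-donor
    mass (within-group similarity ~0.90 at the default); ``pool_noise_sd``
    sets the cross-pair similarity noise (SD ~0.02 at the default).
    """

    n_groups: int = 30
    n_per_group: int | Sequence[int] = 10
    seed: int = 0
    # geography: jittered-grid centroids in an Ethiopia-sized box
    lat_range: tuple[float, float] = (4.0, 14.0)
    lon_range: tuple[float, float] = (34.0, 44.0)
    centroids: Sequence[tuple[float, float]] | None = None
    grid_jitter_deg: float = 0.25
    coord_jitter_deg: float = 0.02
    elev_range: tuple[float, float] = (500.0, 3000.0)
    elevations: Sequence[float] | None = None
    elev_jitter_m: float = 30.0
    # similarity kernel
    alpha_shared: float = 0.50
    beta_geo: float = 0.10
    lambda_geo: float = 0.01  # per km
    alpha_elev: float = 0.005
    delta_elev: float = -2e-6  # per m; zero crossing at 2500 m
    pool_noise_sd: float = 0.025
    self_noise_sd: float = 0.072
    # planted structure
    endogamy: dict[str, float] | float = 0.0
    admixture_edges: list[AdmixtureEdge] = field(default_factory=list)
    trait_cliques: dict[str, list[str]] = field(default_factory=dict)
    trait_boost: float = 0.04
    religion_split: dict[str, float] = field(default_factory=dict)
    # auxiliary tables
    n_traits: int = 31
    trait_state_probs: tuple[float, float, float] = (0.35, 0.25, 0.40)  # Y, N, U
    relative_rate: float = 0.05
    pihat_background_mean: float = 0.02
    pihat_background_sd: float = 0.01
    segment_base_cM: float = 0.6
    segment_boost_scale: float = 40.0  # admixture boost = scale / generations
    trait_segment_boost: float = 4.0
    segment_count_mean: float = 50.0

    def group_names(self) -> list[str]:
        return [f"G{k + 1:02d}" for k in range(self.n_groups)]

    def sizes(self) -> list[int]:
        if isinstance(self.n_per_group, int):
            sizes = [self.n_per_group] * self.n_groups
        else:
            sizes = list(self.n_per_group)
            if len(sizes) != self.n_groups:
                raise ValueError("n_per_group list length must equal n_groups")
        if any(s <= 0 for s in sizes):
            raise ValueError("every group needs at least one individual")
        return sizes

    def endogamy_for(self, group: str) -> float:
        if isinstance(self.endogamy, dict):
            return float(self.endogamy.get(group, 0.0))
        return float(self.endogamy)

    def validate(self) -> None:
        self.sizes()
        if min(self.beta_geo, self.lambda_geo, self.pool_noise_sd, self.self_noise_sd) < 0:
            raise ValueError("rates and noise scales must be non-negative")
        if not 0.0 <= self.relative_rate <= 1.0:
            raise ValueError("relative_rate must be in [0, 1]")
        names = set(self.group_names())
        for g in self.trait_cliques.values():
            unknown = set(g) - names
            if unknown:
                raise ValueError(f"trait clique names unknown groups {sorted(unknown)}")
        for e in self.admixture_edges:
            if e.target not in names or e.source not in names:
                raise ValueError(f"admixture edge uses unknown group: {e}")
        for g in names:
            if self.endogamy_for(g) < 0:
                raise ValueError("endogamy strengths must be non-negative")


@dataclass
class SimulatedCohort:
    """All tables for one synthetic cohort, plus the generator's ground truth."""

    config: ScenarioConfig
    metadata: pd.DataFrame
    internal: pd.DataFrame  # individuals x donor features, rows sum to 1
    external: pd.DataFrame
    segments: pd.DataFrame
    pihat: pd.DataFrame
    traits: pd.DataFrame
    centers_internal: pd.DataFrame
    centers_external: pd.DataFrame
    centers_external_premix: pd.DataFrame
    group_distance_km: pd.DataFrame
    overlap_base: pd.DataFrame
    overlap_internal: pd.DataFrame

    @property
    def provenance(self) -> dict:
        cfg = asdict(self.config)
        cfg["admixture_edges"] = [asdict(e) for e in self.config.admixture_edges]
        return {"generator": "copydist.simulate", "config": cfg}

    def write(self, outdir) -> None:
        """Write every table in the cohort_io formats plus a provenance JSON."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cio.write_metadata(out / "metadata.tsv", self.metadata)
        cio.write_copying_matrix(out / "internal.chunklengths.out", self.internal)
        cio.write_copying_matrix(out / "external.chunklengths.out", self.external)
        cio.write_traits(out / "traits.csv", self.traits)
        popmap = dict(zip(self.metadata["id"], self.metadata["group"]))
        df = self.pihat.copy()
        df["pop1"] = df["iid1"].map(popmap)
        df["pop2"] = df["iid2"].map(popmap)
        cio.write_pihat(out / "pihat.genome", df, out / "popmap.tsv")
        self.segments.to_csv(out / "segments.tsv", sep="\t", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)


def _grid_centroids(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Paired-node layout: grid nodes with two groups per node 30-80 km apart.

    Ethnic groups often live tens of km from their nearest neighbour while
    the cohort spans >1000 km; placing two groups per node samples the short
    range of the distance decay, and the node grid samples the long range.
    """
    n = cfg.n_groups
    n_nodes = (n + 1) // 2
    ncols = int(np.ceil(np.sqrt(n_nodes)))
    nrows = int(np.ceil(n_nodes / ncols))
    lats = np.linspace(cfg.lat_range[0] + 0.5, cfg.lat_range[1] - 0.5, nrows)
    lons = np.linspace(cfg.lon_range[0] + 0.5, cfg.lon_range[1] - 0.5, ncols)
    nodes = np.asarray([(la, lo) for la in lats for lo in lons][:n_nodes], dtype=float)
    nodes += rng.uniform(-cfg.grid_jitter_deg, cfg.grid_jitter_deg, size=nodes.shape)
    pts = []
    for node in nodes:
        pts.append(node)
        if len(pts) < n:
            offset_km = rng.uniform(30.0, 80.0)
            bearing = rng.uniform(0.0, 2.0 * np.pi)
            dlat = offset_km / 111.0 * np.cos(bearing)
            dlon = offset_km / (111.0 * np.cos(np.radians(node[0]))) * np.sin(bearing)
            pts.append(node + [dlat, dlon])
    return np.asarray(pts[:n], dtype=float)


def _pair_overlaps(cfg: ScenarioConfig, D: np.ndarray, H: np.ndarray):
    """Base (both panels) and internal-only pairwise overlap masses."""
    geo = cfg.beta_geo * np.exp(-cfg.lambda_geo * D)
    elev = np.clip(cfg.alpha_elev + cfg.delta_elev * H, 0.0, None)
    base = geo + elev
    np.fill_diagonal(base, 0.0)
    extra = np.zeros_like(base)
    names = cfg.group_names()
    pos = {g: k for k, g in enumerate(names)}
    for clique in cfg.trait_cliques.values():
        idx = [pos[g] for g in clique]
        for i_a, a in enumerate(idx):
            for b in idx[i_a + 1 :]:
                extra[a, b] += cfg.trait_boost
                extra[b, a] += cfg.trait_boost
    return base, base + extra


def _build_centers(
    names: list[str], alpha: np.ndarray, M: np.ndarray, noise_margin: float = 3 * 0.0886
) -> pd.DataFrame:
    """Group centers on the feature basis POOL | SELF_g | PAIR_a_b.

    ``noise_margin`` is the minimum self-donor mass (3 SD of the individual
    noise) needed so that noise clipping stays rare.
    """
    n = len(names)
    pair_feats = [f"PAIR_{names[a]}_{names[b]}" for a in range(n) for b in range(a + 1, n)]
    feats = ["POOL"] + [f"SELF_{g}" for g in names] + pair_feats
    C = pd.DataFrame(0.0, index=names, columns=feats)
    C["POOL"] = alpha
    col = 0
    for a in range(n):
        for b in range(a + 1, n):
            C.iloc[a, 1 + n + col] = M[a, b]
            C.iloc[b, 1 + n + col] = M[a, b]
            col += 1
    for k, g in enumerate(names):
        resid = 1.0 - C.iloc[k].sum()
        if resid < noise_margin:
            raise ValueError(
                f"group {g!r}: self-donor mass {resid:.3f} too small; reduce "
                "alpha_shared, beta_geo or the elevation/trait overlaps"
            )
        C.loc[g, f"SELF_{g}"] = resid
    return C


def simulate_cohort(config: ScenarioConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort; same config (incl. seed) => identical output."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    names = cfg.group_names()
    sizes = cfg.sizes()
    n_groups = cfg.n_groups

    # --- geography -------------------------------------------------------
    if cfg.centroids is not None:
        cent = np.asarray(cfg.centroids, dtype=float)
        if cent.shape != (n_groups, 2):
            raise ValueError("centroids must be one (lat, lon) per group")
    else:
        cent = _grid_centroids(cfg, rng)
    if cfg.elevations is not None:
        elevs = np.asarray(cfg.elevations, dtype=float)
    else:
        elevs = rng.uniform(*cfg.elev_range, size=n_groups)
    D = pairwise_distance_km(cent[:, 0], cent[:, 1])
    H = np.abs(elevs[:, None] - elevs[None, :])

    # --- centers ---------------------------------------------------------
    base, internal_overlap = _pair_overlaps(cfg, D, H)
    alpha_vec = np.full(n_groups, cfg.alpha_shared)
    # self mass must absorb the pool noise fully and most of the private-donor
    # mass; zeta clipping only damps within-group dissimilarity slightly
    margin = 3.0 * cfg.pool_noise_sd + 2.0 * cfg.self_noise_sd
    centers_ext = _build_centers(names, alpha_vec, base, margin)
    centers_int = _build_centers(names, alpha_vec, internal_overlap, margin)
    # endogamy: internal-only shift from pool to self
    for g in names:
        eps = cfg.endogamy_for(g)
        if eps > 0:
            if centers_int.loc[g, "POOL"] <= eps:
                raise ValueError(f"endogamy strength for {g!r} exceeds pool mass")
            centers_int.loc[g, "POOL"] -= eps
            centers_int.loc[g, f"SELF_{g}"] += eps
    centers_ext_premix = centers_ext.copy()
    # admixture: linear center mixing in both panels
    for e in cfg.admixture_edges:
        for C in (centers_int, centers_ext):
            C.loc[e.target] = (1.0 - e.fraction) * C.loc[e.target] + e.fraction * C.loc[e.source]

    # --- per-individual records -----------------------------------------
    ids: list[str] = []
    rows_meta = []
    quad_lat = np.median(cent[:, 0])
    quad_lon = np.median(cent[:, 1])
    group_language_class = {
        g: LANGUAGE_CLASSES[2 * int(cent[k, 0] > quad_lat) + int(cent[k, 1] > quad_lon)]
        for k, g in enumerate(names)
    }
    for k, g in enumerate(names):
        for m in range(sizes[k]):
            iid = f"{g}_{m + 1:03d}"
            ids.append(iid)
            lat = cent[k, 0] + rng.normal(0.0, cfg.coord_jitter_deg)
            lon = cent[k, 1] + rng.normal(0.0, cfg.coord_jitter_deg)
            ev = elevs[k] + rng.normal(0.0, cfg.elev_jitter_m)
            if g in cfg.religion_split:
                religion = RELIGIONS[m % 2]  # alternate Christian / Muslim
            else:
                religion = rng.choice(RELIGIONS, p=RELIGION_PROBS)
            second = rng.choice([None, *(f"lang_{x:02d}" for x in range(10))])
            rows_meta.append(
                dict(
                    id=iid,
                    group=g,
                    lat=lat,
                    lon=lon,
                    elevation_m=ev,
                    language_group=group_language_class[g],
                    first_language=f"lang_of_{g}",
                    second_language=second,
                    religion=religion,
                )
            )
    metadata = pd.DataFrame(rows_meta).set_index("id", drop=False)

    # --- profiles --------------------------------------------------------
    rel_feats = sorted(
        {f"REL_{g}_{r}" for g in cfg.religion_split for r in RELIGIONS[:2]}
    )
    ind_feats = [f"IND_{iid}" for iid in ids]
    feats_int = list(centers_int.columns) + ind_feats + rel_feats
    feats_ext = list(centers_ext.columns) + ind_feats
    prof_int = pd.DataFrame(0.0, index=ids, columns=feats_int)
    prof_ext = pd.DataFrame(0.0, index=ids, columns=feats_ext)
    self_col = {g: f"SELF_{g}" for g in names}
    for iid in ids:
        g = metadata.loc[iid, "group"]
        ci = centers_int.loc[g]
        ce = centers_ext.loc[g]
        self_min = float(min(ci[self_col[g]], ce[self_col[g]]))
        pool_min = float(min(ci["POOL"], ce["POOL"]))
        eta = float(
            np.clip(rng.normal(0.0, cfg.pool_noise_sd), -0.3 * pool_min, 0.3 * self_min)
        )
        zeta = float(np.clip(abs(rng.normal(0.0, cfg.self_noise_sd)), 0.0, 0.6 * self_min))
        row_i = ci.copy()
        row_e = ce.copy()
        for row in (row_i, row_e):
            row["POOL"] += eta
            row[self_col[g]] -= eta + zeta
        if g in cfg.religion_split:
            delta = cfg.religion_split[g]
            religion = metadata.loc[iid, "religion"]
            if religion in RELIGIONS[:2] and row_i["POOL"] > delta:
                row_i["POOL"] -= delta
                prof_int.loc[iid, f"REL_{g}_{religion}"] = delta
        prof_int.loc[iid, row_i.index] = row_i
        prof_int.loc[iid, f"IND_{iid}"] = zeta
        prof_ext.loc[iid, row_e.index] = row_e
        prof_ext.loc[iid, f"IND_{iid}"] = zeta
    prof_int.attrs.update(panel="internal", normalized=True)
    prof_ext.attrs.update(panel="external", normalized=True)

    # --- MRCA segment table (cross-group pairs) --------------------------
    edge_boost = np.zeros((n_groups, n_groups))
    pos = {g: k for k, g in enumerate(names)}
    for e in cfg.admixture_edges:
        b = cfg.segment_boost_scale / e.generations
        edge_boost[pos[e.target], pos[e.source]] += b
        edge_boost[pos[e.source], pos[e.target]] += b
    for clique in cfg.trait_cliques.values():
        for i_a, a in enumerate(clique):
            for b in clique[i_a + 1 :]:
                edge_boost[pos[a], pos[b]] += cfg.trait_segment_boost
                edge_boost[pos[b], pos[a]] += cfg.trait_segment_boost
    group_of = metadata["group"]
    id_arr = np.array(ids)
    gi = np.array([pos[group_of[i]] for i in ids])
    iu, ju = np.triu_indices(len(ids), k=1)
    cross = gi[iu] != gi[ju]
    iu, ju = iu[cross], ju[cross]
    mu = cfg.segment_base_cM + edge_boost[gi[iu], gi[ju]]
    n_seg = rng.poisson(cfg.segment_count_mean, size=iu.size) + 1
    total = rng.gamma(shape=n_seg, scale=mu)
    segments = pd.DataFrame(
        {"iid1": id_arr[iu], "iid2": id_arr[ju], "total_cM": total, "n_segments": n_seg}
    )

    # --- PI_HAT ----------------------------------------------------------
    iu, ju = np.triu_indices(len(ids), k=1)
    background = np.clip(
        rng.normal(cfg.pihat_background_mean, cfg.pihat_background_sd, size=iu.size),
        0.0,
        1.0,
    )
    pihat = pd.DataFrame({"iid1": id_arr[iu], "iid2": id_arr[ju], "pi_hat": background})
    pihat["planted"] = False
    if cfg.relative_rate > 0:
        pihat = inject_relatives(pihat, cfg.relative_rate, rng, groups=group_of)

    # --- trait table ------------------------------------------------------
    trait_names = [f"T{k + 1:02d}" for k in range(cfg.n_traits)]
    clique_names = list(cfg.trait_cliques)
    states = rng.choice(["Y", "N", "U"], size=(n_groups, cfg.n_traits), p=cfg.trait_state_probs)
    traits = pd.DataFrame(states, index=names, columns=trait_names)
    for t, trait in enumerate(clique_names):
        col = trait_names[t % cfg.n_traits]
        traits[col] = rng.choice(["N", "U"], size=n_groups, p=[0.5, 0.5])
        traits.loc[cfg.trait_cliques[trait], col] = "Y"
        traits.rename(columns={col: trait}, inplace=True)
        trait_names[t % cfg.n_traits] = trait
    traits.index.name = "group"

    return SimulatedCohort(
        config=cfg,
        metadata=metadata,
        internal=prof_int,
        external=prof_ext,
        segments=segments,
        pihat=pihat,
        traits=traits,
        centers_internal=centers_int,
        centers_external=centers_ext,
        centers_external_premix=centers_ext_premix,
        group_distance_km=pd.DataFrame(D, index=names, columns=names),
        overlap_base=pd.DataFrame(base, index=names, columns=names),
        overlap_internal=pd.DataFrame(internal_overlap, index=names, columns=names),
    )


def inject_relatives(
    pihat_base: pd.DataFrame,
    rate: float,
    seed,
    groups: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Raise a fraction of pairs to close-relative PI_HAT levels.

    ``rate`` is the fraction of individuals placed into a planted relative
    pair (each pair consumes two); planted pairs get PI_HAT ~ U(0.25, 0.45)
    and are marked in the ``planted`` column.  With ``groups`` given, planted
    pairs are drawn within groups (relatives share a population).  ``seed``
    may be an int or an existing Generator.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    out = pihat_base.copy()
    if "planted" not in out.columns:
        out["planted"] = False
    if rate == 0.0:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    individuals = pd.unique(pd.concat([out["iid1"], out["iid2"]]))
    n_pairs = int(rate * len(individuals) / 2)
    if n_pairs == 0:
        return out
    if groups is not None:
        groups = pd.Series(groups)
        eligible = out.index[out["iid1"].map(groups) == out["iid2"].map(groups)]
    else:
        eligible = out.index
    used: set[str] = set()
    planted_rows = []
    for row in rng.permutation(eligible.to_numpy()):
        a, b = out.loc[row, "iid1"], out.loc[row, "iid2"]
        if a in used or b in used:
            continue
        planted_rows.append(row)
        used.update((a, b))
        if len(planted_rows) == n_pairs:
            break
    out.loc[planted_rows, "pi_hat"] = rng.uniform(0.25, 0.45, size=len(planted_rows))
    out.loc[planted_rows, "planted"] = True
    return out


# ---------------------------------------------------------------------------
# preset scenarios
# ---------------------------------------------------------------------------


def default_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """The neutral study conditions: spatial decay only, no planted effects."""
    return ScenarioConfig(seed=seed, **overrides)


def endogamy_scenario(seed: int = 0, strength: float = 0.15, group: str = "G01", **kw) -> ScenarioConfig:
    """One strongly endogamous group (internal-panel self-copying inflation)."""
    return ScenarioConfig(seed=seed, endogamy={group: strength}, **kw)


def admixture_scenario(
    seed: int = 0,
    target: str = "G01",
    source: str = "G05",
    fraction: float = 0.3,
    generations: float = 10.0,
    **kw,
) -> ScenarioConfig:
    """A recent admixture edge: mixed centers plus long shared segments."""
    return ScenarioConfig(
        seed=seed,
        admixture_edges=[AdmixtureEdge(target, source, fraction, generations)],
        **kw,
    )


def religion_scenario(
    seed: int = 0,
    group: str = "G01",
    strength: float = 0.12,
    n_per_group: int = 12,
    **kw,
) -> ScenarioConfig:
    """One group with religion-stratified ancestry (alternating Christian/Muslim)."""
    return ScenarioConfig(
        seed=seed, religion_split={group: strength}, n_per_group=n_per_group, **kw
    )


def trait_scenario(
    seed: int = 0,
    trait: str = "shared_practice",
    clique: tuple[str, ...] = ("G02", "G08", "G14", "G20"),
    **kw,
) -> ScenarioConfig:
    """Groups sharing a cultural practice with elevated similarity and segments.

    The shared-pool baseline is lowered slightly (0.44) so the clique's extra
    overlap mass fits alongside the spatial kernel for every layout.
    """
    kw.setdefault("alpha_shared", 0.44)
    return ScenarioConfig(seed=seed, trait_cliques={trait: list(clique)}, **kw)
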