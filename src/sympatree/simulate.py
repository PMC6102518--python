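"""Synthetic landscapes of tree communities assembled under allopatric or
sympatric speciation with dispersal limitation.

The generator grows a pure-birth (Yule) phylogeny over a chain of regions
arranged along a latitudinal arc (mimicking a ~2500 km coastal forest belt:
five regions of about ten communities each by default).  Each lineage
carries a geographic range — a set of communities:

* **sympatric** events: both daughters inherit the parent's range, so
  recently split sisters co-occur;
* **allopatric** events: one daughter keeps the parent's range, the other is
  placed in a different region, so sisters never co-occur at birth.

After the tree completes, every species independently disperses to each
unoccupied community with probability ``exp(-d/lambda)`` in its distance
``d`` (km) to the nearest occupied community; a large ``lambda`` emulates
secondary contact after barrier removal.  Node ages are the Yule split
times rescaled so the root sits at ``root_age`` Myr and tips at 0.

Climate covariates are linear gradients (MAT in latitude, MAP in longitude)
plus Gaussian noise, giving the spatially autocorrelated environment the
downstream Mantel machinery expects.  Under sympatric assembly with short
dispersal the dataset carries the signature the pipeline is built to detect:
betaMNTD rising with distance and low-turnover aggregations matching the
true regions; under allopatric assembly with broad dispersal that signal is
absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .communities import CommunityMatrix, HABITATS, haversine_km
from .stats import mantel
from .trees import AgeTable, Node, TaxonPath, Tree

__all__ = [
    "ScenarioConfig",
    "SyntheticDataset",
    "SignatureReport",
    "simulate_tree_and_ranges",
    "climate_field",
    "expected_signature_check",
    "taxonomy_from_tree",
]

logger = logging.getLogger(__name__)

MODES = ("allopatric", "sympatric", "mixed")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic landscape.

    Defaults echo the geometry of a ~49-survey, five-aggregation coastal
    forest study: 5 regions spaced ~620 km apart along a latitudinal arc,
    ~10 communities per region, 300 extant species (20 founding lineages +
    280 speciation events), root at 100 Myr, and a 50 km dispersal scale
    (strong dispersal limitation relative to the inter-region distance).
    """

    mode: str
    seed: int
    fraction_sympatric: Optional[float] = None  # mixed mode only
    n_regions: int = 5
    communities_per_region: int = 10
    n_founders: int = 20
    n_speciation: int = 280
    dispersal_scale_km: float = 50.0
    founder_occupancy: float = 0.4
    range_expansion: float = 0.05  # per-community gain prob. within occupied regions
    root_age: float = 100.0
    lat_start: float = -5.0
    region_spacing_deg: float = 5.6  # ~620 km between region centres
    lon_center: float = -45.0
    community_scatter_deg: float = 0.4
    mat_base: float = 26.0
    mat_per_lat: float = 0.5  # deg C per degree latitude
    mat_noise_sd: float = 0.5
    map_base: float = 1800.0
    map_per_lon: float = 40.0  # mm per degree longitude
    map_noise_sd: float = 100.0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "mixed":
            if self.fraction_sympatric is None or not 0 <= self.fraction_sympatric <= 1:
                raise ValueError("mixed mode needs fraction_sympatric in [0, 1]")
        for name in ("n_regions", "communities_per_region", "n_founders",
                     "n_speciation"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.founder_occupancy <= 1:
            raise ValueError("founder_occupancy must be in (0, 1]")
        if not 0 <= self.range_expansion <= 1:
            raise ValueError("range_expansion must be in [0, 1]")
        if self.dispersal_scale_km < 0 or self.root_age <= 0:
            raise ValueError("dispersal_scale_km >= 0 and root_age > 0 required")

    @property
    def n_communities(self) -> int:
        return self.n_regions * self.communities_per_region

    @property
    def n_species(self) -> int:
        return self.n_founders + self.n_speciation

    def sympatric_probability(self) -> float:
        if self.mode == "sympatric":
            return 1.0
        if self.mode == "allopatric":
            return 0.0
        return float(self.fraction_sympatric)


@dataclass
class SyntheticDataset:
    """Ground-truth container: calibrated tree, communities, sites, labels."""

    tree: Tree
    matrix: CommunityMatrix
    sites: pd.DataFrame
    regions: dict[str, int]
    mode: str
    config: ScenarioConfig


def _layout_sites(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    k = 0
    for r in range(config.n_regions):
        lat_c = config.lat_start - r * config.region_spacing_deg
        dominant = HABITATS[r % len(HABITATS)]
        for _ in range(config.communities_per_region):
            k += 1
            habitat = dominant if rng.random() < 0.7 else \
                HABITATS[rng.integers(len(HABITATS))]
            rows.append(
                {
                    "community": f"c{k:03d}",
                    "latitude": lat_c + rng.normal(0, config.community_scatter_deg),
                    "longitude": config.lon_center
                    + rng.normal(0, config.community_scatter_deg),
                    "habitat": habitat,
                    "region": r,
                }
            )
    return pd.DataFrame(rows)


def climate_field(sites: pd.DataFrame, config: ScenarioConfig,
                  seed: Optional[int] = None) -> pd.DataFrame:
    """Fill MAT (deg C) and MAP (mm) as linear spatial gradients plus noise.

    MAT follows latitude and MAP longitude, so absolute climate differences
    between sites correlate positively with geographic distance by
    construction (zero noise makes the relation exact).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    out = sites.copy()
    n = len(out)
    out["mat"] = (
        config.mat_base
        + config.mat_per_lat * out["latitude"].to_numpy()
        + (rng.normal(0, config.mat_noise_sd, n) if config.mat_noise_sd > 0 else 0.0)
    )
    out["map"] = (
        config.map_base
        + config.map_per_lon * out["longitude"].to_numpy()
        + (rng.normal(0, config.map_noise_sd, n) if config.map_noise_sd > 0 else 0.0)
    )
    return out


def _founder_range(config: ScenarioConfig, rng: np.random.Generator,
                   region: Optional[int] = None) -> tuple[int, frozenset[int]]:
    """A range within one region: each community occupied w.p. founder_occupancy."""
    m = config.communities_per_region
    if region is None:
        region = int(rng.integers(config.n_regions))
    base = region * m
    while True:
        mask = rng.random(m) < config.founder_occupancy
        if mask.any():
            return region, frozenset(int(base + i) for i in np.flatnonzero(mask))


def _grow_tree(config: ScenarioConfig, rng: np.random.Generator
               ) -> tuple[Tree, list[str], list[frozenset[int]]]:
    """Yule growth with range inheritance.

    Returns the calibrated tree plus tip names and tip ranges in matching
    order.
    """
    p_sym = config.sympatric_probability()
    n_comm = config.n_communities
    comm_region = np.repeat(np.arange(config.n_regions), config.communities_per_region)

    def expand(range_set: frozenset[int]) -> frozenset[int]:
        # gain-only range growth inside regions the lineage already occupies,
        # so the sympatric/allopatric co-occurrence invariants are untouched
        if config.range_expansion <= 0:
            return range_set
        gained = set(range_set)
        for r in {int(comm_region[c]) for c in range_set}:
            base = r * config.communities_per_region
            for c in range(base, base + config.communities_per_region):
                if c not in gained and rng.random() < config.range_expansion:
                    gained.add(c)
        return frozenset(gained)

    root = Node()
    founder_counter = 0  # regions are seeded round-robin for balanced coverage
    _, root_range = _founder_range(config, rng,
                                   region=founder_counter % config.n_regions)
    founder_counter += 1
    extant: list[tuple[Node, frozenset[int]]] = [(root, root_range)]
    split_times: dict[int, float] = {}
    t = 0.0
    n_splits = config.n_founders - 1 + config.n_speciation
    for s in range(n_splits):
        t += rng.exponential(1.0 / len(extant))
        i = int(rng.integers(len(extant)))
        node, rng_set = extant.pop(i)
        split_times[id(node)] = t
        d1, d2 = Node(), Node()
        node.add_child(d1)
        node.add_child(d2)
        founder_phase = s < config.n_founders - 1
        if founder_phase:
            r1 = rng_set
            _, r2 = _founder_range(config, rng,
                                   region=founder_counter % config.n_regions)
            founder_counter += 1
        elif rng.random() < p_sym:
            r1 = r2 = rng_set  # sisters co-occur
        else:
            # allopatric: the second daughter is placed in a region disjoint
            # from the parent's range
            occupied = {int(comm_region[c]) for c in rng_set}
            free = [r for r in range(config.n_regions) if r not in occupied]
            r1 = rng_set
            if free:
                _, r2 = _founder_range(config, rng,
                                       region=free[int(rng.integers(len(free)))])
            else:  # parent spans every region (possible in mixed mode)
                region = int(rng.integers(config.n_regions))
                _, cand = _founder_range(config, rng, region=region)
                cand = frozenset(cand - rng_set)
                if not cand:
                    pool = [c for c in range(n_comm) if c not in rng_set]
                    cand = frozenset([int(rng.choice(pool))] if pool else
                                     [int(rng.integers(n_comm))])
                r2 = cand
        if not founder_phase:
            r1, r2 = expand(r1), expand(r2)
        extant.append((d1, r1))
        extant.append((d2, r2))

    # scale split times so the root splits at root_age and tips sit at 0
    t_end = t + rng.exponential(1.0 / len(extant))
    t_root = split_times[id(root)]
    scale = config.root_age / (t_end - t_root)
    tree = Tree(root)
    it_no = 0
    for node in tree.preorder():
        if node.children:
            it_no += 1
            node.name = f"n{it_no:04d}"
            node.age = (t_end - split_times[id(node)]) * scale
            node.fixed = True
        else:
            node.age = 0.0
    tip_names: list[str] = []
    tip_ranges: list[frozenset[int]] = []
    for tip_no, (node, rng_set) in enumerate(extant, start=1):
        node.name = f"sp{tip_no:04d}"
        tip_names.append(node.name)
        tip_ranges.append(rng_set)
    tree.set_lengths_from_ages()
    tree.validate()
    tree.validate_calibration()
    return tree, tip_names, tip_ranges


def _disperse(presence: np.ndarray, dist_km: np.ndarray, scale: float,
              rng: np.random.Generator) -> np.ndarray:
    """Independent per-species colonisation: p = exp(-d_nearest / scale)."""
    if scale <= 0:
        return presence
    out = presence.copy()
    for s in range(presence.shape[0]):
        occ = np.flatnonzero(presence[s])
        d = dist_km[occ].min(axis=0)
        p = np.exp(-d / scale)
        p[occ] = 0.0
        out[s] |= rng.random(presence.shape[1]) < p
    return out


def simulate_tree_and_ranges(config: ScenarioConfig) -> SyntheticDataset:
    """Generate one complete synthetic dataset (deterministic under the seed)."""
    rng = np.random.default_rng(config.seed)
    sites = _layout_sites(config, rng)
    sites = climate_field(sites, config, seed=int(rng.integers(2**31)))
    tree, tip_names, tip_ranges = _grow_tree(config, rng)

    lat = sites["latitude"].to_numpy()
    lon = sites["longitude"].to_numpy()
    dist_km = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])

    n_comm = config.n_communities
    presence = np.zeros((config.n_species, n_comm), dtype=bool)
    for s, rng_set in enumerate(tip_ranges):
        presence[s, list(rng_set)] = True
    presence = _disperse(presence, dist_km, config.dispersal_scale_km, rng)

    for attempt in range(25):
        empty = np.flatnonzero(~presence.any(axis=0))
        if empty.size == 0:
            break
        logger.info("resampling dispersal: %d empty communities (attempt %d)",
                    empty.size, attempt + 1)
        presence = _disperse(presence, dist_km, max(config.dispersal_scale_km, 1.0),
                             rng)
    empty = np.flatnonzero(~presence.any(axis=0))
    for c in empty:  # deterministic fallback: seed with the nearest species
        logger.info("seeding empty community %d with its nearest species", c)
        occ_any = presence.any(axis=1)
        best = None
        for s in np.flatnonzero(occ_any):
            d = dist_km[c, presence[s]].min()
            if best is None or d < best[0]:
                best = (d, s)
        presence[best[1], c] = True

    abundance = np.zeros_like(presence, dtype=int)
    abundance[presence] = rng.geometric(0.3, size=int(presence.sum()))
    matrix = CommunityMatrix(list(sites["community"]), tip_names, abundance.T)
    regions = dict(zip(sites["community"], (int(r) for r in sites["region"])))
    return SyntheticDataset(tree=tree, matrix=matrix, sites=sites,
                            regions=regions, mode=config.mode, config=config)


# ---------------------------------------------------------------------------
# Predicted-signature report
# ---------------------------------------------------------------------------


@dataclass
class SignatureReport:
    """Does a pipeline run show the turnover signature its scenario predicts?

    Sympatric assembly predicts betaMNTD rising significantly with distance
    and lower betaMNTD within regions than between; allopatric assembly with
    broad overlapping ranges predicts an attenuated or absent signal.
    """

    mode: str
    mantel_r_betamntd_km: float
    mantel_p_betamntd_km: float
    within_mean_betamntd: float
    between_mean_betamntd: float
    mantel_r_jaccard_km: float
    mantel_p_jaccard_km: float
    inconclusive: bool = False

    @property
    def betamntd_increases_with_distance(self) -> bool:
        return self.mantel_r_betamntd_km > 0 and self.mantel_p_betamntd_km < 0.05

    @property
    def within_below_between(self) -> bool:
        return self.within_mean_betamntd < self.between_mean_betamntd

    @property
    def jaccard_decays_with_distance(self) -> bool:
        return self.mantel_r_jaccard_km < 0 and self.mantel_p_jaccard_km < 0.05

    @property
    def matches_prediction(self) -> bool:
        if self.inconclusive:
            return False
        sympatric_signature = (
            self.betamntd_increases_with_distance and self.within_below_between
        )
        if self.mode == "sympatric":
            return sympatric_signature
        if self.mode == "allopatric":
            return not self.betamntd_increases_with_distance
        return True  # mixed mode makes no sharp prediction


def expected_signature_check(
    ds: SyntheticDataset,
    pairs: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> SignatureReport:
    """Compare a full pipeline run on ``ds`` with its scenario's prediction.

    ``pairs`` must carry ``jaccard`` and ``beta_mntd`` for every community
    pair (e.g. from :func:`sympatree.metrics.all_pair_metrics`).
    """
    from .communities import geo_distance_matrix, to_square

    for col in ("jaccard", "beta_mntd"):
        if col not in pairs.columns:
            raise ValueError(f"pair table lacks field {col!r}")
    ids = list(ds.matrix.ids)
    km_pairs = geo_distance_matrix(ds.sites)
    KM, _ = to_square(km_pairs, "km", ids)
    B, _ = to_square(pairs, "beta_mntd", ids)
    J, _ = to_square(pairs, "jaccard", ids)
    mb = mantel(KM, B, n_perm=n_perm, seed=seed)
    mj = mantel(KM, J, n_perm=n_perm, seed=seed + 1)

    same_region = np.array(
        [ds.regions[a] == ds.regions[b]
         for a, b in zip(pairs["comm_a"], pairs["comm_b"])]
    )
    bm = pairs["beta_mntd"].to_numpy()
    inconclusive = ds.config.n_regions < 2 or same_region.all()
    return SignatureReport(
        mode=ds.mode,
        mantel_r_betamntd_km=mb.r,
        mantel_p_betamntd_km=mb.p,
        within_mean_betamntd=float(bm[same_region].mean()) if same_region.any()
        else float("nan"),
        between_mean_betamntd=float(bm[~same_region].mean()) if (~same_region).any()
        else float("nan"),
        mantel_r_jaccard_km=mj.r,
        mantel_p_jaccard_km=mj.p,
        inconclusive=inconclusive,
    )


# ---------------------------------------------------------------------------
# Synthetic taxonomy (for the grafting / resolution workflow)
# ---------------------------------------------------------------------------


def taxonomy_from_tree(
    tree: Tree, genus_age: float, family_age: float
) -> tuple[Tree, AgeTable, list[TaxonPath]]:
    """Derive a family/genus/species taxonomy plus a dated backbone megatree.

    Genera are the maximal clades younger than ``genus_age``, families the
    maximal clades younger than ``family_age``; a tip hanging below an older
    node forms a singleton genus.  The backbone is the input tree with every
    genus clade collapsed to a single genus tip and the resolved deep
    topology kept intact — the shape of a real megatree, where grafting
    collapses only congeners into polytomies.  The age table dates every
    interior backbone node at its true age and every multi-species genus at
    its true crown age (singleton genera are left undated, to be
    interpolated).  Returns (backbone, ages, one TaxonPath per species).
    """
    if not tree.is_calibrated():
        raise ValueError("taxonomy_from_tree requires a calibrated tree")
    if not 0 < genus_age < family_age < tree.root.age:
        raise ValueError("need 0 < genus_age < family_age < root age")

    backbone = tree.copy()
    genus_of: dict[str, str] = {}
    family_of_genus: dict[str, str] = {}
    ages: dict[str, float] = {}
    gi = fi = 0

    def clade_tips(node: Node) -> list[str]:
        return [t.name for t in Tree(node).tips()] if node.children else [node.name]

    # collapse genus clades to tips; remember each genus' family label
    stack: list[tuple[Node, Optional[str]]] = [(backbone.root, None)]
    while stack:
        node, family = stack.pop()
        if family is None and node.age <= family_age:
            fi += 1
            family = f"fam{fi:02d}"
        if node.age <= genus_age:
            gi += 1
            gname = f"gen{gi:03d}"
            for tip_name in clade_tips(node):
                genus_of[tip_name] = gname
            family_of_genus[gname] = family
            if node.children:
                ages[gname] = float(node.age)  # true crown age of the genus
            node.children = []
            node.name = gname
            node.age = 0.0
            continue
        stack.extend((c, family) for c in node.children)

    for node in backbone.interior():
        ages[node.name] = float(node.age)

    taxa = [
        TaxonPath(family=family_of_genus[genus_of[tip]], genus=genus_of[tip],
                  terminal=tip)
        for tip in tree.tip_names()
    ]
    return backbone, AgeTable(ages), taxa
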