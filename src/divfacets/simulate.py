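"""Synthetic data generators.

Stand-ins for field data: a pure-birth phylogeny, traits evolved on the
tree (Brownian motion for quantitative traits, a symmetric Mk process for
categorical ones), habitat-structured communities with a tunable
homogenization level, and a continental grid with an endemism hotspot.

Every generator is a pure function of (config, seed): the same seed yields
bit-identical outputs.  A single seeded stream per generator is derived
from the config seed by fixed offsets, so adding one generator never
perturbs another's randomness.
"""

import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .io import (
    CommunityMatrix,
    DataError,
    GridAssemblage,
    Phylogeny,
    TraitTable,
    validate_dataset,
)
from .traitspace import gower_distance

import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "DEFAULT_TRAIT_SCHEMA",
    "simulate_phylogeny",
    "simulate_traits",
    "simulate_communities",
    "simulate_grid",
    "simulate_dataset",
]

# offsets fanned out from the config seed, one stream per generator
_SEED_TREE, _SEED_TRAITS, _SEED_COMMUNITY, _SEED_GRID = 11, 23, 37, 53

# 11 traits mimicking a mixed ecological/morphometric frog trait set
DEFAULT_TRAIT_SCHEMA: list[dict] = [
    {"name": "microhabitat_use", "kind": "categorical", "states": 4, "rate": 0.5},
    {"name": "calling_site", "kind": "categorical", "states": 4, "rate": 0.5},
    {"name": "breeding_seasonality", "kind": "ordinal", "levels": 3, "rate": 1.0},
    {"name": "egg_deposition_site", "kind": "categorical", "states": 3, "rate": 0.5},
    {"name": "egg_type", "kind": "categorical", "states": 3, "rate": 0.5},
    {"name": "tadpole_type", "kind": "categorical", "states": 3, "rate": 0.5},
    {"name": "svl", "kind": "continuous", "rate": 1.0},
    {"name": "head_width", "kind": "continuous", "rate": 1.0},
    {"name": "hindlimb_length", "kind": "continuous", "rate": 1.0},
    {"name": "webbing", "kind": "ordinal", "levels": 4, "rate": 1.0},
    {"name": "terminal_disks", "kind": "binary", "rate": 0.5},
]


@dataclass
class SimulationConfig:
    """Knobs for the synthetic scenario.

    Defaults emulate the study design: 11 + 11 natural and 15 farmland
    sites, species-rich natural pools with low per-site occupancy (high
    turnover), and a small, widespread, trait-nested farmland pool whose
    occupancy is pushed toward 1 by ``homogenization_h``.
    """

    n_species_forest: int = 22
    n_species_savannah: int = 17
    n_species_farmland: int = 19
    shared_farmland_fraction: float = 0.8
    n_sites: dict = field(default_factory=lambda: {"forest": 11, "savannah": 11, "farmland": 15})
    occupancy_natural: float = 0.32
    occupancy_farmland: float = 0.55
    homogenization_h: float = 0.6
    farmland_centrality_quantile: float = 0.5
    trait_schema: list = field(default_factory=lambda: [dict(t) for t in DEFAULT_TRAIT_SCHEMA])
    birth_rate: float = 1.0
    n_species_grid_extra: int = 30
    n_cells: int = 60
    range_size_distribution: dict = field(default_factory=lambda: {"kind": "uniform", "low": 5, "high": 40})
    hotspot_cells: list = field(default_factory=lambda: [28, 29, 30])
    hotspot_endemic_fraction: float = 0.25
    elevation_ranges: dict = field(default_factory=lambda: {
        "forest": (1800, 3050), "savannah": (1280, 1650), "farmland": (1290, 2350)})
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.shared_farmland_fraction, self.occupancy_natural,
                  self.occupancy_farmland, self.homogenization_h,
                  self.farmland_centrality_quantile, self.hotspot_endemic_fraction):
            if not (0.0 <= p <= 1.0):
                raise DataError("probabilities and fractions must lie in [0, 1]")
        for c in (self.n_species_forest, self.n_species_savannah,
                  self.n_species_farmland, self.n_cells):
            if c < 1:
                raise DataError("counts must be positive")

    @property
    def n_tips(self) -> int:
        n_shared = round(self.shared_farmland_fraction * self.n_species_farmland)
        return (self.n_species_forest + self.n_species_savannah
                + (self.n_species_farmland - n_shared) + self.n_species_grid_extra)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "elevation_ranges" in d:
            d["elevation_ranges"] = {k: tuple(v) for k, v in d["elevation_ranges"].items()}
        return cls(**d)


@dataclass
class SyntheticDataset:
    cm: CommunityMatrix
    tt: TraitTable
    phy: Phylogeny
    grid: GridAssemblage
    truth: dict


# ---------------------------------------------------------------------------
# Phylogeny: pure-birth (Yule)
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "birth", "length", "label")

    def __init__(self, birth: float):
        self.children: list[_Node] = []
        self.birth = birth
        self.length: float | None = None
        self.label: str | None = None


def _newick(node: _Node) -> str:
    if node.children:
        inner = ",".join(_newick(c) for c in node.children)
        body = f"({inner})"
    else:
        body = node.label
    return body if node.length is None else f"{body}:{node.length:.10g}"


def simulate_phylogeny(n_tips: int, birth_rate: float = 1.0,
                       seed: int | None = None) -> Phylogeny:
    """Pure-birth (Yule) tree with exactly ``n_tips`` labelled tips.

    Speciation events occur at rate ``birth_rate`` per lineage; after the
    n-th tip appears, one further exponential waiting time (the unrealized
    next speciation) is added so every pendant branch is strictly positive.
    The expected total branch length is (n_tips - 1) / birth_rate.
    """
    if n_tips < 2:
        raise DataError("need at least 2 tips")
    if birth_rate <= 0:
        raise DataError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    root = _Node(0.0)
    active = [_Node(0.0), _Node(0.0)]
    root.children = list(active)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = active.pop(int(rng.integers(k)))
        node.length = t - node.birth
        node.children = [_Node(t), _Node(t)]
        active.extend(node.children)
    t_end = t + rng.exponential(1.0 / (n_tips * birth_rate))
    width = len(str(n_tips))
    for i, leaf in enumerate(active):
        leaf.length = t_end - leaf.birth
        leaf.label = f"sp{i + 1:0{width}d}"
    return Phylogeny.from_newick(_newick(root) + ";")


# ---------------------------------------------------------------------------
# Traits on the tree
# ---------------------------------------------------------------------------

def _normalize_schema(trait_schema: Sequence) -> list[dict]:
    out = []
    for entry in trait_schema:
        if isinstance(entry, dict):
            spec = dict(entry)
        else:  # (name, kind) pair
            spec = {"name": entry[0], "kind": entry[1]}
        if spec.get("kind") not in ("continuous", "ordinal", "categorical", "binary"):
            raise DataError(f"unknown trait kind {spec.get('kind')!r}")
        spec.setdefault("rate", 1.0)
        if spec["kind"] == "ordinal":
            spec.setdefault("levels", 3)
        if spec["kind"] == "categorical":
            spec.setdefault("states", 3)
        if spec["kind"] == "binary":
            spec["states"] = 2
        out.append(spec)
    return out


def _evolve_continuous(phy: Phylogeny, rate: float, rng) -> dict[str, float]:
    tree = phy._tree
    values: dict[int, float] = {id(tree.seed_node): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_val = values[id(node.parent_node)]
        step = 0.0
        if rate > 0 and node.edge.length > 0:
            step = rng.normal(0.0, np.sqrt(rate * node.edge.length))
        values[id(node)] = parent_val + step
        if node.is_leaf():
            out[node.taxon.label.strip()] = values[id(node)]
    return out


def _evolve_mk(phy: Phylogeny, n_states: int, rate: float, rng) -> dict[str, int]:
    """Symmetric Mk: over a branch of length t the probability of leaving
    the current state is (1 - exp(-n_states * rate * t)) * (n_states-1)/n_states,
    uniform over the other states (Jukes–Cantor generalization)."""
    tree = phy._tree
    root_state = int(rng.integers(n_states)) if rate > 0 else 0
    states: dict[int, int] = {id(tree.seed_node): root_state}
    out: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        s = states[id(node.parent_node)]
        if rate > 0 and node.edge.length > 0:
            p_any = 1.0 - np.exp(-n_states * rate * node.edge.length)
            if rng.random() < p_any * (n_states - 1) / n_states:
                others = [x for x in range(n_states) if x != s]
                s = others[int(rng.integers(n_states - 1))]
        states[id(node)] = s
        if node.is_leaf():
            out[node.taxon.label.strip()] = s
    return out


def simulate_traits(phy: Phylogeny, trait_schema: Sequence,
                    seed: int | None = None) -> TraitTable:
    """Evolve a mixed trait table on the tree, one row per tip.

    Continuous traits follow Brownian motion (variance ``rate`` per unit
    branch length, root value 0); ordinal traits are Brownian values binned
    into ``levels`` equal-frequency integer codes; categorical and binary
    traits follow a symmetric Mk process with ``states`` states.
    """
    schema = _normalize_schema(trait_schema)
    if not schema:
        raise DataError("trait schema must be non-empty")
    rng = np.random.default_rng(seed)
    tips = phy.tip_labels
    data: dict[str, list] = {}
    kinds: dict[str, str] = {}
    for spec in schema:
        name, kind = spec["name"], spec["kind"]
        kinds[name] = kind
        if kind == "continuous":
            vals = _evolve_continuous(phy, spec["rate"], rng)
            data[name] = [vals[t] for t in tips]
        elif kind == "ordinal":
            raw = _evolve_continuous(phy, spec["rate"], rng)
            x = np.array([raw[t] for t in tips])
            levels = int(spec["levels"])
            if np.ptp(x) == 0:
                codes = np.zeros(len(tips), dtype=int)
            else:
                edges = np.quantile(x, np.linspace(0, 1, levels + 1)[1:-1])
                codes = np.searchsorted(edges, x, side="right")
            data[name] = [float(c) for c in codes]
        else:  # categorical / binary
            vals = _evolve_mk(phy, int(spec["states"]), spec["rate"], rng)
            data[name] = [f"state{vals[t]}" for t in tips]
    df = pd.DataFrame(data, index=tips)
    return TraitTable(data=df, kinds=kinds,
                      units={n: "mm" for n, k in kinds.items()
                             if k == "continuous"})


# ---------------------------------------------------------------------------
# Habitat-structured communities
# ---------------------------------------------------------------------------

def _assign_pools(cfg: SimulationConfig, tips: list[str], rng,
                  centrality: dict[str, float] | None) -> dict[str, list[str]]:
    """Assign forest/savannah pools and a (trait-nested) farmland pool."""
    n_f, n_s = cfg.n_species_forest, cfg.n_species_savannah
    n_shared = round(cfg.shared_farmland_fraction * cfg.n_species_farmland)
    n_excl = cfg.n_species_farmland - n_shared
    if n_f + n_s + n_excl > len(tips):
        raise DataError("species pools exceed the number of tree tips")
    perm = list(rng.permutation(len(tips)))
    forest = [tips[i] for i in perm[:n_f]]
    savannah = [tips[i] for i in perm[n_f:n_f + n_s]]
    leftover = [tips[i] for i in perm[n_f + n_s:]]
    natural = forest + savannah

    def central_subset(pool: list[str], n_pick: int) -> list[str]:
        if centrality is None:
            idx = rng.choice(len(pool), size=n_pick, replace=False)
            return [pool[i] for i in idx]
        ranked = sorted(pool, key=lambda sp: centrality[sp])
        q = max(n_pick, int(np.ceil(cfg.farmland_centrality_quantile * len(pool))))
        candidates = ranked[:q]
        idx = rng.choice(len(candidates), size=n_pick, replace=False)
        return [candidates[i] for i in idx]

    shared = central_subset(natural, n_shared)
    exclusive = central_subset(leftover, n_excl) if n_excl else []
    return {"forest": forest, "savannah": savannah,
            "farmland": shared + exclusive}


def simulate_communities(cfg: SimulationConfig, phy: Phylogeny,
                         centrality: dict[str, float] | None = None,
                         pools: dict[str, list[str]] | None = None) -> CommunityMatrix:
    """Draw a habitat-structured site x species incidence matrix.

    Natural (forest/savannah) sites draw independently from their habitat
    pool at ``occupancy_natural``, giving high spatial turnover; farmland
    sites draw from the small farmland pool at occupancy
    (1 - h) * occupancy_farmland + h, so h = 1 forces identical farmland
    communities.  ``centrality`` (low = trait-central) nests the farmland
    pool inside the natural trait space.
    """
    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + _SEED_COMMUNITY)
    tips = phy.tip_labels
    if pools is None:
        pools = _assign_pools(cfg, tips, rng, centrality)
    species = sorted(set().union(*pools.values()))
    sp_index = {sp: j for j, sp in enumerate(species)}
    p_farm = (1.0 - cfg.homogenization_h) * cfg.occupancy_farmland + cfg.homogenization_h

    site_ids, habitats, elevations, rows = [], [], [], []
    for habitat in ("forest", "savannah", "farmland"):
        pool = pools[habitat]
        p = p_farm if habitat == "farmland" else cfg.occupancy_natural
        lo, hi = cfg.elevation_ranges[habitat]
        for i in range(cfg.n_sites[habitat]):
            row = np.zeros(len(species), dtype=np.int8)
            draws = rng.random(len(pool)) < p
            for sp, present in zip(pool, draws):
                if present:
                    row[sp_index[sp]] = 1
            rows.append(row)
            site_ids.append(f"{habitat[:4]}_{i + 1:02d}")
            habitats.append(habitat)
            elevations.append(float(rng.uniform(lo, hi)))
    cm = CommunityMatrix(
        site_ids=site_ids, species_ids=species, incidence=np.vstack(rows),
        habitat=habitats, elevation_m=np.array(elevations),
    )
    if cfg.occupancy_natural == 0:
        warnings.warn("occupancy_natural = 0: natural sites are empty")
    return cm


# ---------------------------------------------------------------------------
# Continental grid
# ---------------------------------------------------------------------------

def _draw_range_size(dist: dict, rng) -> int:
    kind = dist.get("kind", "uniform")
    if kind == "uniform":
        return int(rng.integers(int(dist["low"]), int(dist["high"]) + 1))
    if kind == "geometric":
        return int(rng.geometric(1.0 / float(dist["mean"])))
    if kind == "fixed":
        return int(dist["size"])
    raise DataError(f"unknown range size distribution {kind!r}")


def simulate_grid(cfg: SimulationConfig, phy: Phylogeny) -> GridAssemblage:
    """Assign every tree tip a contiguous range on a 1-D strip of cells.

    A ``hotspot_endemic_fraction`` of species become single-cell endemics
    placed uniformly among ``hotspot_cells``; the rest get contiguous
    ranges with sizes from ``range_size_distribution`` (clipped to
    ``n_cells`` with a warning).
    """
    if cfg.n_cells < 2:
        raise DataError("need at least 2 grid cells")
    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + _SEED_GRID)
    species = phy.tip_labels
    n_cells = cfg.n_cells
    inc = np.zeros((n_cells, len(species)), dtype=np.int8)
    hotspot = [c for c in cfg.hotspot_cells if 0 <= c < n_cells]
    n_endemic = round(cfg.hotspot_endemic_fraction * len(species)) if hotspot else 0
    endemic_idx = set(rng.choice(len(species), size=n_endemic, replace=False)) if n_endemic else set()
    clipped = 0
    for j in range(len(species)):
        if j in endemic_idx:
            cell = hotspot[int(rng.integers(len(hotspot)))]
            inc[cell, j] = 1
            continue
        size = _draw_range_size(cfg.range_size_distribution, rng)
        if size > n_cells:
            size = n_cells
            clipped += 1
        start = int(rng.integers(0, n_cells - size + 1))
        inc[start:start + size, j] = 1
    if clipped:
        warnings.warn(f"{clipped} species range(s) clipped to the grid extent")
    lonlat = np.column_stack([np.arange(n_cells, dtype=float), np.zeros(n_cells)])
    return GridAssemblage(
        cell_ids=[f"cell_{i:03d}" for i in range(n_cells)],
        species_ids=list(species), incidence=inc, cell_lonlat=lonlat,
    )


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a fully congruent synthetic dataset from one config.

    Farmland trait nestedness is induced by ranking species by mean Gower
    distance to all others (trait centrality) and drawing the farmland pool
    from the most central ``farmland_centrality_quantile`` of candidates.
    """
    cfg = cfg or SimulationConfig()
    phy = simulate_phylogeny(cfg.n_tips, cfg.birth_rate,
                             seed=None if cfg.seed is None else cfg.seed + _SEED_TREE)
    tt = simulate_traits(phy, cfg.trait_schema,
                         seed=None if cfg.seed is None else cfg.seed + _SEED_TRAITS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dm = gower_distance(tt)
    mean_d = dm.d.sum(axis=1) / (dm.n - 1)
    centrality = dict(zip(dm.labels, mean_d))
    cm = simulate_communities(cfg, phy, centrality=centrality)
    grid = simulate_grid(cfg, phy)
    rep = validate_dataset(cm, tt, phy)
    rep.raise_if_invalid()
    truth = {
        "config": cfg.to_dict(),
        "observed_pools": {h: sorted(cm.species_in(cm.sites_by_habitat(h)))
                           for h in ("forest", "savannah", "farmland")},
    }
    return SyntheticDataset(cm=cm, tt=tt, phy=phy, grid=grid, truth=truth)


def truth_json(ds: SyntheticDataset) -> str:
    return json.dumps(ds.truth, indent=2, sort_keys=True)
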