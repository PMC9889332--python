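"""Data model and file I/O.

Four file-backed domain objects:

* :class:`CommunityMatrix` — binary site x species incidence with habitat
  labels and optional elevations (CSV).
* :class:`TraitTable` — species x trait values with per-trait kind
  declarations (CSV + YAML/JSON sidecar schema).
* :class:`Phylogeny` — rooted tree with branch lengths (Newick, backed by
  :mod:`dendropy`).
* :class:`GridAssemblage` — binary cell x species incidence for the
  continental grid analysis (CSV).

All species-name matching is exact and case-sensitive after stripping
surrounding whitespace; silent fuzzy matches are considered worse than hard
failures.
"""

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HABITATS",
    "TRAIT_KINDS",
    "CommunityMatrix",
    "TraitTable",
    "Phylogeny",
    "GridAssemblage",
    "ValidationReport",
    "read_community_csv",
    "write_community_csv",
    "read_trait_csv",
    "write_trait_csv",
    "read_trait_schema",
    "write_trait_schema",
    "read_newick",
    "write_newick",
    "read_grid_csv",
    "write_grid_csv",
    "validate_dataset",
    "aggregate_sex_means",
]

HABITATS = frozenset({"forest", "savannah", "farmland", "other"})
TRAIT_KINDS = frozenset({"continuous", "ordinal", "categorical", "binary"})

QUANTITATIVE_KINDS = frozenset({"continuous", "ordinal"})


class DataError(ValueError):
    """Raised on malformed or inconsistent input data."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise DataError(f"duplicate {what} id: {x!r}")
        seen.add(x)


def _check_binary(values: np.ndarray, row_ids, col_ids, what: str) -> None:
    bad = np.argwhere((values != 0) & (values != 1))
    if bad.size:
        i, j = bad[0]
        raise DataError(
            f"non-binary value {values[i, j]!r} in {what} "
            f"at row {row_ids[i]!r}, column {col_ids[j]!r}"
        )


# ---------------------------------------------------------------------------
# CommunityMatrix
# ---------------------------------------------------------------------------

@dataclass
class CommunityMatrix:
    """Binary site x species incidence with per-site habitat labels."""

    site_ids: list[str]
    species_ids: list[str]
    incidence: np.ndarray  # shape (n_sites, n_species), values in {0, 1}
    habitat: list[str]
    elevation_m: np.ndarray | None = None  # per-site, metres a.s.l.

    def __post_init__(self) -> None:
        self.site_ids = [str(s).strip() for s in self.site_ids]
        self.species_ids = [str(s).strip() for s in self.species_ids]
        _check_unique(self.site_ids, "site")
        _check_unique(self.species_ids, "species")
        self.incidence = np.asarray(self.incidence)
        if self.incidence.shape != (len(self.site_ids), len(self.species_ids)):
            raise DataError("incidence shape does not match site/species ids")
        _check_binary(self.incidence, self.site_ids, self.species_ids, "community matrix")
        self.incidence = self.incidence.astype(np.int8)
        self.habitat = [str(h).strip().lower() for h in self.habitat]
        if len(self.habitat) != len(self.site_ids):
            raise DataError("one habitat label required per site")
        for s, h in zip(self.site_ids, self.habitat):
            if h not in HABITATS:
                raise DataError(f"unknown habitat {h!r} for site {s!r}")
        if self.elevation_m is not None:
            self.elevation_m = np.asarray(self.elevation_m, dtype=float)
            if self.elevation_m.shape != (len(self.site_ids),):
                raise DataError("one elevation per site required")
            if np.nanmin(self.elevation_m) < 0:
                raise DataError("elevations must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def site_index(self, site: str) -> int:
        try:
            return self.site_ids.index(site)
        except ValueError:
            raise KeyError(f"unknown site {site!r}") from None

    def species_at(self, site: str) -> set[str]:
        row = self.incidence[self.site_index(site)]
        return {sp for sp, v in zip(self.species_ids, row) if v}

    def species_in(self, sites: Iterable[str]) -> set[str]:
        """Pooled species set over ``sites``."""
        out: set[str] = set()
        for s in sites:
            out |= self.species_at(s)
        return out

    def sites_by_habitat(self, *habitats: str) -> list[str]:
        wanted = {h.lower() for h in habitats}
        return [s for s, h in zip(self.site_ids, self.habitat) if h in wanted]

    def subset_sites(self, sites: Sequence[str]) -> "CommunityMatrix":
        idx = [self.site_index(s) for s in sites]
        return CommunityMatrix(
            site_ids=[self.site_ids[i] for i in idx],
            species_ids=list(self.species_ids),
            incidence=self.incidence[idx].copy(),
            habitat=[self.habitat[i] for i in idx],
            elevation_m=None if self.elevation_m is None else self.elevation_m[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.incidence, index=self.site_ids, columns=self.species_ids)
        df.insert(0, "habitat", self.habitat)
        if self.elevation_m is not None:
            df.insert(1, "elevation_m", self.elevation_m)
        df.index.name = "site_id"
        return df


def read_community_csv(path) -> CommunityMatrix:
    df = pd.read_csv(path, dtype=str)
    cols = list(df.columns)
    if not cols or cols[0] != "site_id" or "habitat" not in cols[:3]:
        raise DataError("community CSV must start with columns site_id, habitat[, elevation_m]")
    has_elev = "elevation_m" in cols
    meta = {"site_id", "habitat"} | ({"elevation_m"} if has_elev else set())
    species = [c for c in cols if c not in meta]
    site_ids = [s.strip() for s in df["site_id"].tolist()]
    values = np.empty((len(df), len(species)), dtype=np.int8)
    for j, sp in enumerate(species):
        for i, raw in enumerate(df[sp].tolist()):
            txt = str(raw).strip()
            if txt not in ("0", "1"):
                raise DataError(
                    f"non-binary value {txt!r} at row {site_ids[i]!r}, column {sp!r}"
                )
            values[i, j] = int(txt)
    elev = None
    if has_elev:
        elev = pd.to_numeric(df["elevation_m"], errors="coerce").to_numpy()
    return CommunityMatrix(
        site_ids=site_ids,
        species_ids=species,
        incidence=values,
        habitat=df["habitat"].tolist(),
        elevation_m=elev,
    )


def write_community_csv(cm: CommunityMatrix, path) -> None:
    cm.to_frame().to_csv(path)


# ---------------------------------------------------------------------------
# TraitTable
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Species x trait values with declared per-trait kinds.

    ``data`` is indexed by species id; quantitative columns are float (NaN =
    missing), categorical/binary columns are object (None/NaN = missing).
    """

    data: pd.DataFrame
    kinds: dict[str, str]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = [str(s).strip() for s in self.data.index]
        _check_unique(list(self.data.index), "species")
        if not self.kinds:
            raise DataError("trait table needs at least one trait column")
        for name, kind in self.kinds.items():
            if kind not in TRAIT_KINDS:
                raise DataError(f"unknown trait kind {kind!r} for trait {name!r}")
            if name not in self.data.columns:
                raise DataError(f"declared trait {name!r} missing from table")
        undeclared = [c for c in self.data.columns if c not in self.kinds]
        if undeclared:
            raise DataError(f"undeclared trait columns: {undeclared}")
        for name, kind in self.kinds.items():
            if kind in QUANTITATIVE_KINDS:
                try:
                    col = pd.to_numeric(self.data[name])
                except (ValueError, TypeError) as exc:
                    raise DataError(f"non-numeric value in {kind} trait {name!r}: {exc}")
                if np.isinf(col.to_numpy(dtype=float)).any():
                    raise DataError(f"non-finite value in {kind} trait {name!r}")
                self.data[name] = col.astype(float)
        n_missing = int(self.data.isna().sum().sum())
        if n_missing:
            warnings.warn(f"trait table has {n_missing} missing value(s)", stacklevel=3)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)


def read_trait_schema(path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a YAML/JSON sidecar declaring trait kinds (and optional units)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kinds: dict[str, str] = {}
    units: dict[str, str] = {}
    for name, decl in raw.items():
        if isinstance(decl, str):
            kinds[name] = decl
        else:
            kinds[name] = decl["kind"]
            if "unit" in decl:
                units[name] = decl["unit"]
    return kinds, units


def write_trait_schema(kinds: Mapping[str, str], path, units: Mapping[str, str] | None = None) -> None:
    units = units or {}
    out = {}
    for name, kind in kinds.items():
        out[name] = {"kind": kind, "unit": units[name]} if name in units else kind
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def read_trait_csv(path, schema: Mapping[str, str], units: Mapping[str, str] | None = None) -> TraitTable:
    df = pd.read_csv(path, dtype=str)
    if "species_id" not in df.columns:
        raise DataError("trait CSV must have a species_id column")
    df = df.set_index("species_id")
    return TraitTable(data=df, kinds=dict(schema), units=dict(units or {}))


def write_trait_csv(tt: TraitTable, path) -> None:
    df = tt.data.copy()
    df.index.name = "species_id"
    df.to_csv(path)


def aggregate_sex_means(raw: pd.DataFrame, species_col: str = "species_id",
                        sex_col: str = "sex") -> pd.DataFrame:
    """Collapse per-specimen morphometrics to one row per species.

    Mean of per-sex means, so unbalanced sex sampling does not bias species
    values.  Stand-in rule — no canonical aggregation exists for such tables.
    """
    value_cols = [c for c in raw.columns if c not in (species_col, sex_col)]
    per_sex = raw.groupby([species_col, sex_col])[value_cols].mean()
    return per_sex.groupby(level=0).mean()


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

class Phylogeny:
    """Rooted phylogeny with branch lengths, backed by a dendropy tree.

    Exposes an indexed edge table so diversity code can treat the tree as a
    set of weighted edges plus per-tip root paths.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._index_edges()

    def _index_edges(self) -> None:
        root = self._tree.seed_node
        lengths: list[float] = []
        tip_paths: dict[str, frozenset[int]] = {}
        node_edge: dict[int, int] = {}  # id(node) -> edge index
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise DataError("missing branch length in tree (no default imputation)")
            if node.edge.length < 0:
                raise DataError("negative branch length in tree")
            node_edge[id(node)] = len(lengths)
            lengths.append(float(node.edge.length))
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None:
                raise DataError("unnamed tip in tree")
            label = leaf.taxon.label.strip()
            if label in tip_paths:
                raise DataError(f"duplicate tip label {label!r}")
            path = []
            node = leaf
            while node is not root:
                path.append(node_edge[id(node)])
                node = node.parent_node
            tip_paths[label] = frozenset(path)
        self.edge_lengths: np.ndarray = np.asarray(lengths, dtype=float)
        self.tip_paths: dict[str, frozenset[int]] = tip_paths

    # -- basic accessors ---------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return list(self.tip_paths)

    @property
    def n_tips(self) -> int:
        return len(self.tip_paths)

    @property
    def n_edges(self) -> int:
        return self.edge_lengths.size

    @property
    def total_length(self) -> float:
        return float(self.edge_lengths.sum())

    def path_edges(self, species: Iterable[str]) -> set[int]:
        """Union of root-to-tip path edge indices over ``species``."""
        out: set[int] = set()
        for sp in species:
            try:
                out |= self.tip_paths[sp]
            except KeyError:
                raise KeyError(f"unknown tip {sp!r}") from None
        return out

    def tip_edge_matrix(self, species_order: Sequence[str]) -> np.ndarray:
        """Boolean (len(species_order), n_edges) root-path membership matrix."""
        m = np.zeros((len(species_order), self.n_edges), dtype=bool)
        for i, sp in enumerate(species_order):
            try:
                m[i, list(self.tip_paths[sp])] = True
            except KeyError:
                raise KeyError(f"unknown tip {sp!r}") from None
        return m

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise DataError(f"newick parse error: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True,
        )
        return s.strip() + "\n"

    def copy(self) -> "Phylogeny":
        return Phylogeny.from_newick(self.to_newick())

    def __repr__(self) -> str:
        return f"Phylogeny(n_tips={self.n_tips}, total_length={self.total_length:.4g})"


def read_newick(path) -> Phylogeny:
    text = Path(path).read_text()
    return Phylogeny.from_newick(text)


def write_newick(phy: Phylogeny, path) -> None:
    Path(path).write_text(phy.to_newick())


# ---------------------------------------------------------------------------
# GridAssemblage
# ---------------------------------------------------------------------------

@dataclass
class GridAssemblage:
    """Binary cell x species incidence for the continental-scale analysis."""

    cell_ids: list[str]
    species_ids: list[str]
    incidence: np.ndarray
    cell_lonlat: np.ndarray | None = None  # (n_cells, 2) centroid degrees

    def __post_init__(self) -> None:
        self.cell_ids = [str(c).strip() for c in self.cell_ids]
        self.species_ids = [str(s).strip() for s in self.species_ids]
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.species_ids, "species")
        self.incidence = np.asarray(self.incidence)
        if self.incidence.shape != (len(self.cell_ids), len(self.species_ids)):
            raise DataError("incidence shape does not match cell/species ids")
        _check_binary(self.incidence, self.cell_ids, self.species_ids, "grid")
        self.incidence = self.incidence.astype(np.int8)
        if self.cell_lonlat is not None:
            self.cell_lonlat = np.asarray(self.cell_lonlat, dtype=float)
            if self.cell_lonlat.shape != (len(self.cell_ids), 2):
                raise DataError("cell_lonlat must be (n_cells, 2)")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell_index(self, cell: str) -> int:
        try:
            return self.cell_ids.index(cell)
        except ValueError:
            raise KeyError(f"unknown cell {cell!r}") from None

    def species_at(self, cell: str) -> set[str]:
        row = self.incidence[self.cell_index(cell)]
        return {sp for sp, v in zip(self.species_ids, row) if v}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.incidence, index=self.cell_ids, columns=self.species_ids)
        if self.cell_lonlat is not None:
            df.insert(0, "lon", self.cell_lonlat[:, 0])
            df.insert(1, "lat", self.cell_lonlat[:, 1])
        df.index.name = "cell_id"
        return df


def read_grid_csv(path) -> GridAssemblage:
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "cell_id":
        raise DataError("grid CSV must start with a cell_id column")
    df = df.set_index("cell_id")
    lonlat = None
    if "lon" in df.columns and "lat" in df.columns:
        lonlat = np.column_stack([
            pd.to_numeric(df.pop("lon")).to_numpy(),
            pd.to_numeric(df.pop("lat")).to_numpy(),
        ])
    species = list(df.columns)
    values = np.empty((len(df), len(species)), dtype=np.int8)
    for j, sp in enumerate(species):
        for i, raw in enumerate(df[sp].tolist()):
            txt = str(raw).strip()
            if txt not in ("0", "1"):
                raise DataError(
                    f"non-binary value {txt!r} at row {df.index[i]!r}, column {sp!r}"
                )
            values[i, j] = int(txt)
    return GridAssemblage(
        cell_ids=list(df.index), species_ids=species, incidence=values,
        cell_lonlat=lonlat,
    )


def write_grid_csv(grid: GridAssemblage, path) -> None:
    grid.to_frame().to_csv(path)


# ---------------------------------------------------------------------------
# Cross-file validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    species_missing_from_tree: list[str] = field(default_factory=list)
    species_missing_from_traits: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_invalid(self) -> None:
        if self.errors:
            raise DataError("; ".join(self.errors))


def validate_dataset(cm: CommunityMatrix, tt: TraitTable | None = None,
                     phy: Phylogeny | None = None) -> ValidationReport:
    """Cross-check name congruence between community, traits and tree.

    Errors iff a community species lacks a tree tip or trait row; unused
    tips/trait rows and never-observed species only warn.
    """
    rep = ValidationReport()
    community = set(cm.species_ids)
    if phy is not None:
        tips = set(phy.tip_labels)
        missing = sorted(community - tips)
        if missing:
            rep.species_missing_from_tree = missing
            rep.errors.append(f"species missing from tree: {missing}")
        unused = sorted(tips - community)
        if unused:
            rep.warnings.append(f"tree tips unused by community: {unused}")
    if tt is not None:
        have = set(tt.species_ids)
        missing = sorted(community - have)
        if missing:
            rep.species_missing_from_traits = missing
            rep.errors.append(f"species missing from trait table: {missing}")
        unused = sorted(have - community)
        if unused:
            rep.warnings.append(f"trait rows unused by community: {unused}")
    never_seen = [sp for sp, tot in zip(cm.species_ids, cm.incidence.sum(axis=0)) if tot == 0]
    if never_seen:
        rep.warnings.append(f"species occurring in zero sites: {never_seen}")
    empty_sites = [s for s, tot in zip(cm.site_ids, cm.incidence.sum(axis=1)) if tot == 0]
    if empty_sites:
        rep.warnings.append(f"sites with zero species: {empty_sites}")
    return rep
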