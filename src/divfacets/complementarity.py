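"""Continental grid analysis: per-cell richness and PD, weighted species
and phylogenetic endemism, richness-corrected complementarity ratios, the
cell-replacement counterfactual, and max-scaling for mapping.

Complementarity is implemented as weighted endemism divided by the cell's
own diversity (we/S and pe/PD): cells whose species (or branches) occur in
few other cells score near 1, cells of widespread species score near 1/N.
The uncorrected weighted-endemism values are also emitted for sensitivity.
"""

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DataError, GridAssemblage, Phylogeny

__all__ = [
    "cell_diversity",
    "species_complementarity",
    "phylo_complementarity",
    "replace_cells",
    "scale_to_max",
    "cell_table",
]


def _check_grid_species(grid: GridAssemblage, phy: Phylogeny) -> None:
    missing = sorted(set(grid.species_ids) - set(phy.tip_labels))
    if missing:
        raise DataError(
            f"grid species missing from tree (graft them first): {missing}"
        )


def _cell_edge_matrix(grid: GridAssemblage, phy: Phylogeny) -> np.ndarray:
    """Boolean (n_cells, n_edges): edge lies on a rooted path of the cell."""
    tip_edges = phy.tip_edge_matrix(grid.species_ids)
    return (grid.incidence.astype(bool) @ tip_edges) > 0


def cell_diversity(grid: GridAssemblage, phy: Phylogeny) -> pd.DataFrame:
    """Per-cell species richness and rooted Faith's PD."""
    _check_grid_species(grid, phy)
    s = grid.incidence.sum(axis=1).astype(int)
    cell_edges = _cell_edge_matrix(grid, phy)
    pd_vals = cell_edges @ phy.edge_lengths
    return pd.DataFrame(
        {"cell_id": grid.cell_ids, "S": s, "pd": pd_vals}
    ).set_index("cell_id")


def species_complementarity(grid: GridAssemblage) -> pd.DataFrame:
    """Weighted endemism and richness-corrected species complementarity.

    occ_s = number of cells holding species s; we_i = sum over the cell's
    species of 1/occ_s; comp_s = we_i / S_i.  Weighted endemism conserves
    species count: sum over cells of we equals the number of species
    occupying at least one cell.  Empty cells get NaN complementarity.
    """
    if grid.n_cells == 0:
        raise DataError("empty grid")
    inc = grid.incidence.astype(float)
    occ = inc.sum(axis=0)
    inv_occ = np.where(occ > 0, 1.0 / np.where(occ > 0, occ, 1.0), 0.0)
    we = inc @ inv_occ
    s = inc.sum(axis=1)
    comp = np.where(s > 0, we / np.where(s > 0, s, 1.0), np.nan)
    return pd.DataFrame(
        {"cell_id": grid.cell_ids, "we": we, "comp_s": comp}
    ).set_index("cell_id")


def phylo_complementarity(grid: GridAssemblage, phy: Phylogeny) -> pd.DataFrame:
    """Phylogenetic endemism and PD-corrected phylogenetic complementarity.

    For each edge b of length L_b, occ_b counts cells whose species place b
    on a rooted root-to-tip path; pe_i = sum over the cell's edges of
    L_b/occ_b and comp_pd = pe_i / pd_i.  Sum over cells of pe equals the
    total length of edges occupied anywhere.
    """
    _check_grid_species(grid, phy)
    cell_edges = _cell_edge_matrix(grid, phy)
    occ = cell_edges.sum(axis=0)
    inv_occ = np.where(occ > 0, 1.0 / np.where(occ > 0, occ, 1.0), 0.0)
    pe = cell_edges @ (phy.edge_lengths * inv_occ)
    pd_vals = cell_edges @ phy.edge_lengths
    comp = np.where(pd_vals > 0, pe / np.where(pd_vals > 0, pd_vals, 1.0), np.nan)
    return pd.DataFrame(
        {"cell_id": grid.cell_ids, "pe": pe, "comp_pd": comp}
    ).set_index("cell_id")


def replace_cells(grid: GridAssemblage,
                  replacements: Mapping[str, Iterable[str]]) -> GridAssemblage:
    """Overwrite named cells' species sets; all other cells untouched.

    The cell count is unchanged — this is the counterfactual used to drop a
    region's observed assemblages into the continental grid.
    """
    species_index = {sp: j for j, sp in enumerate(grid.species_ids)}
    inc = grid.incidence.copy()
    for cell_id, species in replacements.items():
        i = grid.cell_index(cell_id)  # raises on unknown cell
        row = np.zeros(len(grid.species_ids), dtype=np.int8)
        for sp in species:
            sp = str(sp).strip()
            if sp not in species_index:
                raise DataError(f"unknown species {sp!r} in replacement for {cell_id!r}")
            row[species_index[sp]] = 1
        inc[i] = row
    return GridAssemblage(
        cell_ids=list(grid.cell_ids), species_ids=list(grid.species_ids),
        incidence=inc,
        cell_lonlat=None if grid.cell_lonlat is None else grid.cell_lonlat.copy(),
    )


def scale_to_max(values: Sequence[float]) -> np.ndarray:
    """Divide by the maximum finite value; NaN entries propagate as NaN."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0 or np.nanmax(finite) <= 0:
        raise DataError("scale_to_max needs at least one positive finite value")
    return values / finite.max()


def cell_table(grid: GridAssemblage, phy: Phylogeny) -> pd.DataFrame:
    """One row per cell: S, pd, we, pe, comp_s, comp_pd plus scaled columns."""
    out = cell_diversity(grid, phy)
    out = out.join(species_complementarity(grid)).join(phylo_complementarity(grid, phy))
    for col in ("S", "pd", "we", "pe", "comp_s", "comp_pd"):
        out[f"{col}_scaled"] = scale_to_max(out[col].to_numpy())
    return out
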