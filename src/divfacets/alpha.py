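"""Per-assemblage diversity: richness, convex-hull functional richness,
Faith's PD, and the tip-graft rule for species missing from the tree."""

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .io import CommunityMatrix, DataError, Phylogeny
from .traitspace import TraitSpace

__all__ = [
    "DiversityRecord",
    "richness",
    "functional_richness",
    "faith_pd",
    "graft_species",
    "assemblage_diversity",
    "alpha_table",
]


@dataclass
class DiversityRecord:
    assemblage_id: str
    richness: int
    fric: float  # convex-hull volume; NaN when undefined
    pd: float


def richness(cm: CommunityMatrix, site: str) -> int:
    """Species richness of one site (count of 1-entries in its row)."""
    return int(cm.incidence[cm.site_index(site)].sum())


def functional_richness(ts: TraitSpace, species: Iterable[str]) -> float:
    """Convex-hull volume of the species' trait-space coordinates.

    NaN (with a warning) when fewer than k+1 species are given or the
    points are affinely degenerate — reporting 0 would conflate "no
    volume" with "volume undefined".
    """
    pts = ts.points_for(list(species))
    if pts.shape[0] < ts.k + 1:
        warnings.warn(
            f"functional richness undefined for {pts.shape[0]} species in "
            f"{ts.k}-D trait space"
        )
        return float("nan")
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        warnings.warn("degenerate (affinely dependent) point set; hull undefined")
        return float("nan")


def faith_pd(phy: Phylogeny, species: Iterable[str], include_root: bool = True) -> float:
    """Faith's PD: summed branch length connecting a species set.

    With ``include_root`` (the default convention here) this is the total
    length of edges on the union of the species' root-to-tip paths, so a
    single species contributes its full root path.  Without it, only edges
    below the species' most recent common ancestor are counted (edges above
    the MRCA are exactly those shared by every root path).
    """
    species = list(species)
    if not species:
        warnings.warn("faith_pd of an empty species set is 0")
        return 0.0
    paths = []
    for sp in species:
        try:
            paths.append(phy.tip_paths[sp])
        except KeyError:
            raise KeyError(f"unknown tip {sp!r}") from None
    union = frozenset().union(*paths)
    if include_root:
        edges = union
    else:
        edges = union - frozenset.intersection(*paths)
    idx = list(edges)
    return float(phy.edge_lengths[idx].sum()) if idx else 0.0


def graft_species(phy: Phylogeny, new_species: str, sister: str,
                  fraction: float = 0.5) -> Phylogeny:
    """Attach a missing species onto its closest relative's terminal branch.

    The sister's pendant branch of length L is split ``fraction * L`` below
    the tip; the new species attaches there with a pendant of the same
    length, so total tree length grows by exactly ``fraction * L``.
    """
    if not (0.0 <= fraction <= 1.0):
        raise DataError("fraction must lie in [0, 1]")
    if new_species in phy.tip_paths:
        raise DataError(f"tip {new_species!r} already present in tree")
    if sister not in phy.tip_paths:
        raise DataError(f"sister tip {sister!r} not found in tree")
    out = phy.copy()
    tree = out._tree
    sister_node = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label.strip() == sister:
            sister_node = leaf
            break
    assert sister_node is not None
    length = float(sister_node.edge.length)
    parent = sister_node.parent_node
    if parent is None:
        raise DataError("cannot graft onto a single-tip tree root")
    parent.remove_child(sister_node)
    joint = parent.new_child(edge_length=(1.0 - fraction) * length)
    joint.add_child(sister_node)
    sister_node.edge.length = fraction * length
    taxon = tree.taxon_namespace.require_taxon(label=new_species)
    joint.new_child(taxon=taxon, edge_length=fraction * length)
    out._index_edges()
    return out


def assemblage_diversity(cm: CommunityMatrix, ts: TraitSpace | None,
                         phy: Phylogeny | None, sites: Sequence[str],
                         assemblage_id: str | None = None,
                         include_root: bool = True) -> DiversityRecord:
    """All three diversity facets of the species pooled over ``sites``.

    One site gives alpha diversity; all sites of a habitat class give that
    habitat's gamma diversity.
    """
    sites = list(sites)
    if not sites:
        raise DataError("assemblage_diversity needs at least one site")
    pooled = sorted(cm.species_in(sites))
    fric = float("nan")
    if ts is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fric = functional_richness(ts, pooled) if pooled else float("nan")
    pd_val = 0.0
    if phy is not None and pooled:
        pd_val = faith_pd(phy, pooled, include_root=include_root)
    return DiversityRecord(
        assemblage_id=assemblage_id or "+".join(sites),
        richness=len(pooled),
        fric=fric,
        pd=pd_val,
    )


def alpha_table(cm: CommunityMatrix, ts: TraitSpace | None = None,
                phy: Phylogeny | None = None) -> pd.DataFrame:
    """Per-site DiversityRecord rows as a DataFrame (one row per site)."""
    rows = []
    for site, hab in zip(cm.site_ids, cm.habitat):
        rec = assemblage_diversity(cm, ts, phy, [site], assemblage_id=site)
        rows.append({
            "site_id": site, "habitat": hab, "richness": rec.richness,
            "fric": rec.fric, "pd": rec.pd,
        })
    return pd.DataFrame(rows)
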