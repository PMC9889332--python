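"""Pairwise Sørensen dissimilarity in taxonomic, functional and
phylogenetic form.

Functional beta rests on convex-hull intersection volumes in the shared
trait space; phylogenetic beta is the PhyloSor construction over rooted
root-to-tip path sets, consistent with the rooted Faith's PD used for
alpha diversity.
"""

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

from .alpha import faith_pd
from .io import CommunityMatrix, DataError, Phylogeny
from .traitspace import TraitSpace

__all__ = [
    "BetaMatrix",
    "sorensen_taxonomic",
    "sorensen_taxonomic_partition",
    "hull_intersection_volume",
    "sorensen_functional",
    "sorensen_phylogenetic",
    "beta_matrix",
    "beta_pairs_table",
]

FACETS = ("taxonomic", "functional", "phylogenetic")


@dataclass
class BetaMatrix:
    site_ids: list[str]
    facet: str
    b: np.ndarray  # symmetric, entries in [0,1] or NaN

    def __post_init__(self) -> None:
        if self.facet not in FACETS:
            raise DataError(f"unknown facet {self.facet!r}")
        self.b = np.asarray(self.b, dtype=float)
        n = len(self.site_ids)
        if self.b.shape != (n, n):
            raise DataError("beta matrix shape must match site ids")

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.site_ids), k=1)
        return self.b[iu]


# ---------------------------------------------------------------------------
# Scalar dissimilarities
# ---------------------------------------------------------------------------

def sorensen_taxonomic(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Sørensen dissimilarity (b+c)/(2a+b+c) on two species sets."""
    sa, sb = set(set_a), set(set_b)
    if not sa or not sb:
        warnings.warn("Sørensen undefined for an empty assemblage")
        return float("nan")
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    return (b + c) / (2 * a + b + c)


def sorensen_taxonomic_partition(set_a: Iterable[str], set_b: Iterable[str]) -> dict[str, float]:
    """Baselga partition of taxonomic Sørensen into turnover + nestedness.

    Returns {"total", "turnover", "nestedness"} with
    turnover = Simpson dissimilarity min(b,c)/(a+min(b,c)) and
    nestedness = total - turnover.  Optional extra; the headline analyses
    use the total only.
    """
    sa, sb = set(set_a), set(set_b)
    if not sa or not sb:
        return {"total": float("nan"), "turnover": float("nan"), "nestedness": float("nan")}
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    total = (b + c) / (2 * a + b + c)
    m = min(b, c)
    turnover = m / (a + m) if (a + m) else 0.0
    return {"total": total, "turnover": turnover, "nestedness": total - turnover}


def _hull_or_none(points: np.ndarray) -> ConvexHull | None:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < points.shape[1] + 1:
        return None
    try:
        return ConvexHull(points)
    except QhullError:
        return None


def hull_intersection_volume(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Volume of the intersection of two full-dimensional convex hulls.

    The two hulls' half-space representations are stacked, a strictly
    interior point of the intersection is found as the Chebyshev centre by
    linear programming, and the intersection polytope is re-hulled.  An
    infeasible or zero-radius centre means the interiors are disjoint
    (volume 0); a degenerate input hull yields NaN with a warning.
    """
    hull_a = _hull_or_none(points_a)
    hull_b = _hull_or_none(points_b)
    if hull_a is None or hull_b is None:
        warnings.warn("degenerate input hull; intersection volume undefined")
        return float("nan")
    halfspaces = np.vstack([hull_a.equations, hull_b.equations])  # A x + b <= 0
    dim = halfspaces.shape[1] - 1
    norms = np.linalg.norm(halfspaces[:, :-1], axis=1)
    # Chebyshev centre: maximize r subject to A x + ||A_i|| r <= -b, r >= 0
    res = linprog(
        c=np.r_[np.zeros(dim), -1.0],
        A_ub=np.column_stack([halfspaces[:, :-1], norms]),
        b_ub=-halfspaces[:, -1],
        bounds=[(None, None)] * dim + [(0, None)],
        method="highs",
    )
    if not res.success or res.x[-1] <= 1e-12:
        return 0.0
    interior = res.x[:dim]
    try:
        hs = HalfspaceIntersection(halfspaces, interior)
        return float(ConvexHull(hs.intersections).volume)
    except QhullError:
        return 0.0  # measure-zero intersection


def sorensen_functional(ts: TraitSpace, set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Sørensen dissimilarity on convex-hull volumes in trait space.

    With shared hull-intersection volume a and exclusive volumes
    b = V(A) - a, c = V(B) - a: (b+c)/(2a+b+c).  NaN when either hull is
    undefined (fewer than k+1 affinely independent species).
    """
    pa = ts.points_for(list(set_a))
    pb = ts.points_for(list(set_b))
    hull_a = _hull_or_none(pa)
    hull_b = _hull_or_none(pb)
    if hull_a is None or hull_b is None:
        warnings.warn("undefined hull; functional Sørensen is NaN")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = hull_intersection_volume(pa, pb)
    va, vb = hull_a.volume, hull_b.volume
    a = min(a, va, vb)  # clip float noise from re-hulling
    b = va - a
    c = vb - a
    if (2 * a + b + c) == 0:
        return float("nan")
    return (b + c) / (2 * a + b + c)


def sorensen_phylogenetic(phy: Phylogeny, set_a: Iterable[str],
                          set_b: Iterable[str]) -> float:
    """PhyloSor dissimilarity: 1 - 2*shared branch length / (PD_A + PD_B).

    Shared branch length is the total length of edges lying on rooted
    root-to-tip paths of both species sets.
    """
    sa, sb = list(set_a), list(set_b)
    if not sa or not sb:
        warnings.warn("phylogenetic Sørensen undefined for an empty assemblage")
        return float("nan")
    edges_a = phy.path_edges(sa)
    edges_b = phy.path_edges(sb)
    shared = list(edges_a & edges_b)
    bl_shared = float(phy.edge_lengths[shared].sum()) if shared else 0.0
    pd_a = faith_pd(phy, sa)
    pd_b = faith_pd(phy, sb)
    if pd_a + pd_b == 0:
        return float("nan")
    return 1.0 - 2.0 * bl_shared / (pd_a + pd_b)


# ---------------------------------------------------------------------------
# Matrix over site pairs
# ---------------------------------------------------------------------------

def beta_matrix(cm: CommunityMatrix, facet: str, ts: TraitSpace | None = None,
                phy: Phylogeny | None = None,
                sites: Sequence[str] | None = None) -> BetaMatrix:
    """Pairwise dissimilarity among ``sites`` (default: all) for one facet."""
    if facet not in FACETS:
        raise DataError(f"unknown facet {facet!r}")
    sites = list(sites) if sites is not None else list(cm.site_ids)
    if len(sites) < 2:
        raise DataError("beta_matrix needs at least 2 sites")
    if facet == "functional" and ts is None:
        raise DataError("functional beta requires a TraitSpace")
    if facet == "phylogenetic" and phy is None:
        raise DataError("phylogenetic beta requires a Phylogeny")
    sets = [cm.species_at(s) for s in sites]
    n = len(sites)
    b = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                if facet == "taxonomic":
                    v = sorensen_taxonomic(sets[i], sets[j])
                elif facet == "functional":
                    v = sorensen_functional(ts, sets[i], sets[j])
                else:
                    v = sorensen_phylogenetic(phy, sets[i], sets[j])
                b[i, j] = b[j, i] = v
    n_nan = int(np.isnan(b[np.triu_indices(n, k=1)]).sum())
    if n_nan:
        warnings.warn(f"{n_nan} undefined {facet} beta pair(s) set to NaN")
    return BetaMatrix(site_ids=sites, facet=facet, b=b)


def beta_pairs_table(cm: CommunityMatrix, facet: str, ts: TraitSpace | None = None,
                     phy: Phylogeny | None = None,
                     within_habitat: bool = True) -> pd.DataFrame:
    """Long-format pair table (site_i, site_j, habitat_class, dissimilarity).

    With ``within_habitat`` only pairs from the same habitat class are
    emitted, mirroring per-habitat beta summaries.
    """
    bm = beta_matrix(cm, facet, ts=ts, phy=phy)
    hab = dict(zip(cm.site_ids, cm.habitat))
    rows = []
    for i, si in enumerate(bm.site_ids):
        for j in range(i + 1, len(bm.site_ids)):
            sj = bm.site_ids[j]
            if within_habitat and hab[si] != hab[sj]:
                continue
            rows.append({
                "site_i": si, "site_j": sj, "facet": facet,
                "habitat_class": hab[si] if hab[si] == hab[sj] else "mixed",
                "dissimilarity": bm.b[i, j],
            })
    return pd.DataFrame(rows)
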