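"""Habitat-level machinery: subsampled gamma diversity, sample-based
species-accumulation curves, elevation filtering, group contrasts and
cross-facet correlations."""

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .alpha import assemblage_diversity
from .io import CommunityMatrix, DataError, Phylogeny
from .traitspace import TraitSpace

__all__ = [
    "GammaSummary",
    "AccumulationCurve",
    "HabitatContrast",
    "subsample_gamma",
    "accumulation_curve",
    "elevation_filter",
    "compare_groups",
    "permutation_group_test",
    "facet_correlation",
]


@dataclass
class GammaSummary:
    habitat_class: str
    facet: str
    draws: int
    median: float
    sd: float
    min: float
    max: float
    values: np.ndarray = field(repr=False, default=None)


@dataclass
class AccumulationCurve:
    k: np.ndarray
    expected_richness: np.ndarray
    sd: np.ndarray | None = None  # permutation mode only


@dataclass
class HabitatContrast:
    metric_name: str
    group_labels: tuple[str, str]
    t: float
    df: float
    p: float
    medians: tuple[float, float]
    iqrs: tuple[float, float]


# ---------------------------------------------------------------------------
# Subsampled gamma
# ---------------------------------------------------------------------------

def _facet_gamma(cm: CommunityMatrix, ts, phy, sites, facet: str) -> float:
    rec = assemblage_diversity(cm, ts, phy, sites, assemblage_id="gamma")
    if facet == "taxonomic":
        return float(rec.richness)
    if facet == "functional":
        return rec.fric
    if facet == "phylogenetic":
        return rec.pd
    raise DataError(f"unknown facet {facet!r}")


def subsample_gamma(cm: CommunityMatrix, ts: TraitSpace | None,
                    phy: Phylogeny | None, group_sizes: Mapping[str, int],
                    facet: str, n_draws: int = 1000,
                    seed: int | None = None,
                    habitat_class: str = "natural") -> GammaSummary:
    """Gamma diversity of repeated site subsamples, summarized over draws.

    Each draw samples, per habitat, the requested number of sites uniformly
    without replacement, pools species across all drawn sites, and computes
    the facet's gamma.  Draws are independent; repeating a site combination
    across draws is permitted.  Deterministic under ``seed``.
    """
    if n_draws < 1:
        raise DataError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    pools: list[list[str]] = []
    sizes: list[int] = []
    for habitat, count in group_sizes.items():
        available = cm.sites_by_habitat(habitat)
        if count > len(available):
            raise DataError(
                f"requested {count} sites from habitat {habitat!r} "
                f"but only {len(available)} available"
            )
        pools.append(available)
        sizes.append(int(count))
    values = np.empty(n_draws)
    for d in range(n_draws):
        drawn: list[str] = []
        for pool, size in zip(pools, sizes):
            idx = rng.choice(len(pool), size=size, replace=False)
            drawn.extend(pool[i] for i in idx)
        values[d] = _facet_gamma(cm, ts, phy, drawn, facet)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise DataError("all gamma draws undefined (NaN)")
    return GammaSummary(
        habitat_class=habitat_class, facet=facet, draws=n_draws,
        median=float(np.median(finite)), sd=float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0,
        min=float(finite.min()), max=float(finite.max()), values=values,
    )


# ---------------------------------------------------------------------------
# Species-accumulation curves
# ---------------------------------------------------------------------------

def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -np.inf
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def accumulation_curve(cm: CommunityMatrix, sites: Sequence[str] | None = None,
                       mode: str = "exact", n_perm: int = 1000,
                       seed: int | None = None) -> AccumulationCurve:
    """Sample-based species accumulation over k = 1..n sites.

    Exact mode is the analytic sample-based rarefaction
    S(k) = sum_s [1 - C(n - n_s, k) / C(n, k)], with n_s the number of
    sites occupied by species s; permutation mode averages observed
    richness over random site orderings and also reports a per-k SD.
    """
    sites = list(sites) if sites is not None else list(cm.site_ids)
    n = len(sites)
    if n < 1:
        raise DataError("accumulation_curve needs at least one site")
    idx = [cm.site_index(s) for s in sites]
    sub = cm.incidence[idx]
    n_s = sub.sum(axis=0)  # per-species occupied-site counts
    ks = np.arange(1, n + 1)
    if mode == "exact":
        expected = np.empty(n)
        for i, k in enumerate(ks):
            log_cnk = _log_comb(n, int(k))
            miss = np.array([
                np.exp(_log_comb(n - int(m), int(k)) - log_cnk) if m > 0 else 0.0
                for m in n_s
            ])
            # species never observed contribute 0 to every k
            present = n_s > 0
            expected[i] = float(np.sum(1.0 - miss[present]))
        return AccumulationCurve(k=ks, expected_richness=expected)
    if mode == "permutation":
        rng = np.random.default_rng(seed)
        acc = np.zeros((n_perm, n))
        for p in range(n_perm):
            order = rng.permutation(n)
            seen = np.zeros(sub.shape[1], dtype=bool)
            for i, site_row in enumerate(order):
                seen |= sub[site_row] > 0
                acc[p, i] = seen.sum()
        return AccumulationCurve(
            k=ks, expected_richness=acc.mean(axis=0), sd=acc.std(axis=0, ddof=1),
        )
    raise DataError(f"unknown accumulation mode {mode!r}")


# ---------------------------------------------------------------------------
# Elevation filter
# ---------------------------------------------------------------------------

def elevation_filter(cm: CommunityMatrix, max_elevation_m: float) -> CommunityMatrix:
    """Restrict the community to sites at or below ``max_elevation_m``.

    Species left with zero occurrences are retained (and will be flagged by
    validation) so downstream name congruence is unchanged.
    """
    if cm.elevation_m is None or np.isnan(cm.elevation_m).any():
        raise DataError("elevation_filter requires an elevation for every site")
    keep = [s for s, e in zip(cm.site_ids, cm.elevation_m) if e <= max_elevation_m]
    if not keep:
        raise DataError(f"no sites at or below {max_elevation_m} m")
    out = cm.subset_sites(keep)
    lost = int((out.incidence.sum(axis=0) == 0).sum()) - int((cm.incidence.sum(axis=0) == 0).sum())
    if lost > 0:
        warnings.warn(f"{lost} species no longer occur after elevation filtering")
    return out


# ---------------------------------------------------------------------------
# Group contrasts and correlations
# ---------------------------------------------------------------------------

def _iqr(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75, 25])  # numpy default = type-7 linear
    return float(q75 - q25)


def compare_groups(x: Sequence[float], y: Sequence[float],
                   metric_name: str = "metric",
                   group_labels: tuple[str, str] = ("x", "y"),
                   equal_var: bool = False) -> HabitatContrast:
    """Two-sided t-test between two value groups plus medians and IQRs.

    Welch's unequal-variance form by default (Welch–Satterthwaite df);
    ``equal_var=True`` gives the pooled Student variant.  When applied to
    pairwise beta values the observations are non-independent; a warning is
    emitted and :func:`permutation_group_test` offers a sounder alternative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise DataError("each group needs at least 2 finite values")
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
        raise DataError("t statistic undefined: both groups constant and equal")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return HabitatContrast(
        metric_name=metric_name, group_labels=group_labels,
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
        medians=(float(np.median(x)), float(np.median(y))),
        iqrs=(_iqr(x), _iqr(y)),
    )


def permutation_group_test(x: Sequence[float], y: Sequence[float],
                           n_perm: int = 9999, seed: int | None = None) -> float:
    """Two-sided permutation p-value for a difference in group means.

    Label-permutation alternative to the t-test for non-independent values
    such as pairwise dissimilarities.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    obs = abs(x.mean() - y.mean())
    n_x = x.size
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[:n_x].mean() - pooled[n_x:].mean()) >= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def facet_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """OLS simple regression of y on x: returns (R^2, two-sided slope p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise DataError("facet_correlation needs at least 3 paired points")
    if np.var(x) == 0:
        raise DataError("zero variance in predictor")
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2), float(res.pvalue)
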