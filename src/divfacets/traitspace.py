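"""Mixed-trait dissimilarity and ordination.

Gower distances over mixed continuous/ordinal/categorical/binary traits,
then non-metric multidimensional scaling (Kruskal stress-1, pool-adjacent-
violators monotone regression, SMACOF-style configuration updates) into a
common low-dimensional trait space shared by all assemblages.
"""

import warnings
from dataclasses import dataclass

import numpy as np

from .io import QUANTITATIVE_KINDS, DataError, TraitTable

__all__ = [
    "DistanceMatrix",
    "TraitSpace",
    "gower_distance",
    "nmds_embed",
    "stress1",
    "pava",
]


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise DataError("distance matrix shape must match labels")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise DataError("distance matrix must be symmetric")
        if np.nanmax(np.abs(np.diag(self.d))) > 1e-12:
            raise DataError("distance matrix must have zero diagonal")
        if np.nanmin(self.d) < 0:
            raise DataError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]


@dataclass
class TraitSpace:
    """Per-species coordinates in a k-dimensional embedding."""

    labels: list[str]
    coords: np.ndarray  # (n_species, k)
    stress: float
    k: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.labels), self.k):
            raise DataError("coords shape must be (n_labels, k)")
        if not np.all(np.isfinite(self.coords)):
            raise DataError("coordinates must be finite")
        if not (0.0 <= self.stress <= 1.0):
            raise DataError("stress must lie in [0, 1]")

    def points_for(self, species) -> np.ndarray:
        index = {sp: i for i, sp in enumerate(self.labels)}
        try:
            rows = [index[sp] for sp in species]
        except KeyError as exc:
            raise KeyError(f"unknown species {exc.args[0]!r}") from None
        return self.coords[rows]


# ---------------------------------------------------------------------------
# Gower distance
# ---------------------------------------------------------------------------

def gower_distance(tt: TraitTable, weights: dict[str, float] | None = None) -> DistanceMatrix:
    """Pairwise Gower dissimilarity on a mixed trait table.

    d(i,j) = sum_t w_t * delta_ijt * d_ijt / sum_t w_t * delta_ijt, with
    delta_ijt = 1 iff trait t is non-missing for both species.  Continuous
    and ordinal traits contribute |x_i - x_j| / range_t (ordinal on numeric
    level codes, the simple Gower treatment, not Podani's tie correction);
    categorical and binary traits contribute 0 on match, 1 otherwise.
    Traits with zero range are excluded with a warning; a pair sharing no
    non-missing trait is an error.
    """
    n = len(tt.species_ids)
    if n < 2:
        raise DataError("need at least 2 species for Gower distances")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for name in tt.trait_names:
        w = 1.0 if weights is None else float(weights.get(name, 1.0))
        if w == 0:
            continue
        kind = tt.kinds[name]
        col = tt.data[name]
        if kind in QUANTITATIVE_KINDS:
            x = col.to_numpy(dtype=float)
            present = np.isfinite(x)
            if present.sum() < 2:
                warnings.warn(f"trait {name!r} has <2 observed values; excluded")
                continue
            rng = np.nanmax(x) - np.nanmin(x)
            if rng == 0:
                warnings.warn(f"trait {name!r} has zero range; excluded from Gower")
                continue
            diff = np.abs(x[:, None] - x[None, :]) / rng
            share = present[:, None] & present[None, :]
            num += np.where(share, np.nan_to_num(diff), 0.0) * w
            den += share * w
        else:
            vals = col.to_numpy(dtype=object)
            present = np.array([v is not None and v == v for v in vals])
            if present.sum() < 2:
                warnings.warn(f"trait {name!r} has <2 observed values; excluded")
                continue
            mismatch = np.array(
                [[0.0 if a == b else 1.0 for b in vals] for a in vals]
            )
            share = present[:, None] & present[None, :]
            num += np.where(share, mismatch, 0.0) * w
            den += share * w
    off = ~np.eye(n, dtype=bool)
    if np.any(den[off] == 0):
        i, j = np.argwhere((den == 0) & off)[0]
        raise DataError(
            f"species {tt.species_ids[i]!r} and {tt.species_ids[j]!r} share no traits"
        )
    d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # symmetrize away float noise
    return DistanceMatrix(labels=list(tt.species_ids), d=d)


# ---------------------------------------------------------------------------
# Monotone regression and stress
# ---------------------------------------------------------------------------

def pava(y: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Pool-adjacent-violators: least-squares non-decreasing fit to ``y``."""
    y = np.asarray(y, dtype=float)
    if w is None:
        w = np.ones_like(y)
    # blocks as (value, weight, count) merged while decreasing
    vals: list[float] = []
    wts: list[float] = []
    cnt: list[int] = []
    for yi, wi in zip(y, w):
        vals.append(float(yi))
        wts.append(float(wi))
        cnt.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v2, w2, c2 = vals.pop(), wts.pop(), cnt.pop()
            v1, w1, c1 = vals.pop(), wts.pop(), cnt.pop()
            wt = w1 + w2
            vals.append((v1 * w1 + v2 * w2) / wt)
            wts.append(wt)
            cnt.append(c1 + c2)
    out = np.empty_like(y)
    pos = 0
    for v, c in zip(vals, cnt):
        out[pos:pos + c] = v
        pos += c
    return out


def _monotone_fit(d: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """PAVA fit of embedded distances against dissimilarity order.

    Ties in ``delta`` are handled by Kruskal's primary approach: within a
    tie block the distances are pre-sorted ascending, so tied dissimilarities
    may be fitted at unequal values without penalty.
    """
    order = np.lexsort((d, delta))
    dhat = np.empty_like(d)
    dhat[order] = pava(d[order])
    return dhat


def stress1(coords: np.ndarray, dm: DistanceMatrix) -> float:
    """Kruskal stress-1 of the monotone-regressed fit of ``coords`` to ``dm``.

    sqrt(sum (d - dhat)^2 / sum d^2) over all unordered pairs; returns 1.0
    for the degenerate all-coincident configuration.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != dm.n:
        raise DataError("coords rows must match distance matrix size")
    if dm.n < 2:
        raise DataError("need at least 2 points")
    delta = dm.condensed()
    d = _pairwise(coords)
    denom = float(np.sum(d ** 2))
    if denom == 0.0:
        return 0.0 if np.all(delta == 0) else 1.0
    dhat = _monotone_fit(d, delta)
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def _pairwise(coords: np.ndarray) -> np.ndarray:
    n = coords.shape[0]
    iu = np.triu_indices(n, k=1)
    diff = coords[iu[0]] - coords[iu[1]]
    return np.sqrt(np.sum(diff ** 2, axis=1))


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson scaling of a square distance matrix, used as warm start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)


def _guttman_update(x: np.ndarray, dhat_sq: np.ndarray) -> np.ndarray:
    """One SMACOF majorization step toward disparities ``dhat_sq`` (square form)."""
    n = x.shape[0]
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt(np.sum(diff ** 2, axis=2))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, dhat_sq / np.where(d > 0, d, 1.0), 0.0)
    b = -ratio
    np.fill_diagonal(b, 0.0)
    np.fill_diagonal(b, -b.sum(axis=1))
    return (b @ x) / n


def nmds_embed(dm: DistanceMatrix, k: int = 3, n_starts: int = 20,
               max_iter: int = 300, tol: float = 1e-7,
               seed: int | None = None) -> TraitSpace:
    """Non-metric MDS of a dissimilarity matrix into k dimensions.

    Runs ``n_starts`` initial configurations (one Torgerson/classical-MDS
    warm start, the rest random), each refined by alternating PAVA monotone
    regression with a SMACOF configuration update until the stress-1 change
    drops below ``tol``.  The lowest-stress solution is centred at the
    origin and rotated to its principal axes for deterministic orientation.
    """
    n = dm.n
    if n <= k:
        raise DataError(f"need more than k={k} points, got {n}")
    if n_starts < 1:
        raise DataError("n_starts must be >= 1")
    delta = dm.condensed()
    if np.all(delta == delta[0]):
        warnings.warn("all dissimilarities equal; NMDS solution is degenerate")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)

    best_x = None
    best_stress = np.inf
    for start in range(n_starts):
        if start == 0:
            x = _classical_mds(dm.d, k)
            if not np.all(np.isfinite(x)):
                x = rng.standard_normal((n, k))
        else:
            x = rng.standard_normal((n, k))
        prev = np.inf
        stress = 1.0
        for _ in range(max_iter):
            d = _pairwise(x)
            denom = float(np.sum(d ** 2))
            if denom == 0.0:
                break
            dhat = _monotone_fit(d, delta)
            stress = float(np.sqrt(np.sum((d - dhat) ** 2) / denom))
            if abs(prev - stress) < tol:
                break
            prev = stress
            # normalize disparities to the scale of the distances before the
            # majorization step so the configuration does not collapse
            scale = np.sqrt(denom / max(np.sum(dhat ** 2), 1e-300))
            dhat_sq = np.zeros((n, n))
            dhat_sq[iu] = dhat * scale
            dhat_sq += dhat_sq.T
            x = _guttman_update(x, dhat_sq)
        d = _pairwise(x)
        denom = float(np.sum(d ** 2))
        stress = (
            1.0 if denom == 0.0
            else float(np.sqrt(np.sum((d - _monotone_fit(d, delta)) ** 2) / denom))
        )
        if stress < best_stress:
            best_stress = stress
            best_x = x

    assert best_x is not None
    coords = _align(best_x)
    return TraitSpace(labels=list(dm.labels), coords=coords,
                      stress=min(max(best_stress, 0.0), 1.0), k=k)


def _align(x: np.ndarray) -> np.ndarray:
    """Centre and rotate to principal axes; fix each axis sign."""
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    y = x @ vt.T
    for j in range(y.shape[1]):
        col = y[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            y[:, j] = -col
    return y
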