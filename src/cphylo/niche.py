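"""Environmental-space niche overlap and randomization tests.

The approach of Broennimann et al. (2012): climate at every background
cell is reduced to two principal components; occurrence and background
densities are kernel-smoothed on a regular grid over the background's
PC extent; the occupancy surface z is the availability-corrected ratio
o/e, normalized to sum to one.  Overlap between two occupancy surfaces
is Schoener's D = 1 - 0.5 * sum |z1 - z2|, and its significance is
assessed with randomization tests:

* equivalency -- pool both occurrence sets and re-split them into
  groups of the original sizes; rejects when the observed niches are
  distinguishable at all;
* similarity -- redraw one set from its background availability;
  rejects when the observed overlap exceeds what random niches give.

p-values use the two-sided add-one convention
``min(1, 2 (1 + #more-extreme) / (1 + reps))``, so with 100 repetitions
the attainable floor is 2/101 = 0.0198 and every p is an even multiple
of 1/101.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from cphylo.errors import ArgumentError, DegenerateDataError

log = logging.getLogger(__name__)


# -- PCA over the background environment ------------------------------


@dataclass
class EnvPCA:
    """Standardized PCA of the background climate.

    Loadings are columns of ``loadings``; the sign convention makes the
    largest-magnitude entry of each loading vector positive.
    """

    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # (n_vars, n_axes)
    variance_fractions: np.ndarray

    def transform(self, table: np.ndarray, n_axes: int = 2) -> np.ndarray:
        z = (np.asarray(table, dtype=float) - self.means) / self.sds
        return z @ self.loadings[:, :n_axes]


def env_pca(background: np.ndarray) -> EnvPCA:
    """PCA on standardized variables over the full background."""
    X = np.asarray(background, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise ArgumentError("background table needs >= 3 rows and >= 2 variables")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if len(zero):
        raise ArgumentError(f"zero-variance variable(s) at column(s) {zero.tolist()}")
    Z = (X - means) / sds
    # SVD of the standardized matrix: right singular vectors are loadings
    _, svals, Vt = np.linalg.svd(Z, full_matrices=False)
    var = svals**2 / (X.shape[0] - 1)
    fractions = var / X.shape[1]  # total variance of standardized data = n_vars
    loadings = Vt.T
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return EnvPCA(means=means, sds=sds, loadings=loadings, variance_fractions=fractions)


# -- occupancy densities ----------------------------------------------


@dataclass
class NicheDensity:
    """Normalized occupancy surface over the (PC1, PC2) grid."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    z: np.ndarray  # (R, R), sums to 1

    def same_geometry(self, other: "NicheDensity") -> bool:
        return (
            self.z.shape == other.z.shape
            and np.allclose(self.x_edges, other.x_edges)
            and np.allclose(self.y_edges, other.y_edges)
        )


def _silverman(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for one axis."""
    n = len(x)
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread == 0:
        spread = 1e-6
    return 0.9 * spread * n ** (-0.2)


def _grid_kde(points: np.ndarray, gx: np.ndarray, gy: np.ndarray, hx: float, hy: float) -> np.ndarray:
    """Separable Gaussian KDE evaluated on the grid (len(gx), len(gy))."""
    dx = (gx[:, None] - points[None, :, 0]) / hx
    dy = (gy[:, None] - points[None, :, 1]) / hy
    kx = np.exp(-0.5 * dx**2)
    ky = np.exp(-0.5 * dy**2)
    dens = kx @ ky.T
    return dens / (2 * np.pi * hx * hy * len(points))


def density_grid(
    occ_scores: np.ndarray,
    background_scores: np.ndarray,
    R: int = 100,
    bandwidth: "str | tuple[float, float]" = "silverman",
) -> NicheDensity:
    """Availability-corrected occurrence density on an R x R PC grid.

    Occurrence and background densities use the same per-axis Silverman
    bandwidths estimated from the background (or an explicit
    ``(hx, hy)`` pair); z = o / e where the background density is
    positive (0 elsewhere), renormalized.  Occurrences outside the
    background extent are clipped to it with a logged warning count.
    """
    occ = np.asarray(occ_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if occ.ndim != 2 or occ.shape[1] != 2 or bg.ndim != 2 or bg.shape[1] != 2:
        raise ArgumentError("scores must be (n, 2) arrays of PC pairs")
    if len(occ) < 5:
        raise ArgumentError("need >= 5 occurrences to build a density grid")
    if isinstance(bandwidth, str) and bandwidth != "silverman":
        raise ArgumentError(f"unknown bandwidth rule {bandwidth!r}")

    lo = bg.min(axis=0)
    hi = bg.max(axis=0)
    outside = np.any((occ < lo) | (occ > hi), axis=1)
    if outside.any():
        log.warning("%d occurrence score(s) outside background extent; clipped", int(outside.sum()))
        occ = np.clip(occ, lo, hi)

    gx = np.linspace(lo[0], hi[0], R)
    gy = np.linspace(lo[1], hi[1], R)
    if isinstance(bandwidth, str):
        hx, hy = _silverman(bg[:, 0]), _silverman(bg[:, 1])
    else:
        hx, hy = bandwidth
    o = _grid_kde(occ, gx, gy, hx, hy)
    e = _grid_kde(bg, gx, gy, hx, hy)
    # availability threshold: treat cells below a tiny fraction of the
    # peak background density as environmentally unavailable
    avail = e > e.max() * 1e-6
    z = np.zeros_like(o)
    z[avail] = o[avail] / e[avail]
    total = z.sum()
    if total <= 0:
        raise DegenerateDataError("occupancy surface is identically zero")
    return NicheDensity(x_edges=gx, y_edges=gy, z=z / total)


def schoener_D(z1: NicheDensity, z2: NicheDensity) -> float:
    """Schoener's D = 1 - 0.5 sum |z1 - z2|; 0 = disjoint, 1 = identical."""
    if not z1.same_geometry(z2):
        raise ArgumentError("density grids have mismatched geometry")
    return float(1.0 - 0.5 * np.abs(z1.z - z2.z).sum())


# -- randomization tests ----------------------------------------------


def _two_sided_p(n_extreme: int, reps: int) -> float:
    return min(1.0, 2.0 * (1 + n_extreme) / (1 + reps))


def equivalency_test(
    occ1: np.ndarray,
    occ2: np.ndarray,
    background: np.ndarray,
    reps: int = 100,
    seed: int = 0,
    R: int = 100,
) -> tuple[float, np.ndarray, float]:
    """Niche equivalency randomization test on PC scores.

    Pools both occurrence sets, re-splits them (without replacement)
    into groups of the original sizes each repetition, and compares the
    observed Schoener's D with the null distribution.  Returns
    ``(D_obs, null D values, p)``; low D relative to the null rejects
    equivalency.
    """
    occ1 = np.asarray(occ1, dtype=float)
    occ2 = np.asarray(occ2, dtype=float)
    if reps < 1:
        raise ArgumentError("reps must be >= 1")
    if len(occ1) + len(occ2) < 10:
        raise DegenerateDataError("fewer than 10 combined occurrences")
    rng = np.random.default_rng(seed)

    z1 = density_grid(occ1, background, R=R)
    z2 = density_grid(occ2, background, R=R)
    d_obs = schoener_D(z1, z2)

    pool = np.vstack([occ1, occ2])
    n1 = len(occ1)
    null = np.empty(reps)
    for r in range(reps):
        perm = rng.permutation(len(pool))
        g1 = pool[perm[:n1]]
        g2 = pool[perm[n1:]]
        null[r] = schoener_D(
            density_grid(g1, background, R=R), density_grid(g2, background, R=R)
        )
    p = _two_sided_p(int(np.sum(null <= d_obs)), reps)
    return d_obs, null, p


def similarity_test(
    occ1: np.ndarray,
    occ2: np.ndarray,
    background2: np.ndarray,
    reps: int = 100,
    seed: int = 0,
    R: int = 100,
    background1: np.ndarray | None = None,
) -> tuple[float, np.ndarray, float]:
    """Niche similarity randomization test (direction 1 -> 2).

    Each repetition draws ``len(occ2)`` pseudo-occurrences with
    replacement from the availability distribution of background 2,
    rebuilds its occupancy surface, and recomputes D against the
    observed niche 1.  High observed D relative to the null rejects
    "no more similar than random".  Returns ``(D_obs, null D, p)``.
    """
    occ1 = np.asarray(occ1, dtype=float)
    occ2 = np.asarray(occ2, dtype=float)
    background2 = np.asarray(background2, dtype=float)
    if reps < 1:
        raise ArgumentError("reps must be >= 1")
    if len(background2) == 0:
        raise ArgumentError("empty background")
    bg1 = background2 if background1 is None else np.asarray(background1, dtype=float)
    rng = np.random.default_rng(seed)

    z1 = density_grid(occ1, bg1, R=R)
    z2 = density_grid(occ2, background2, R=R)
    if not z1.same_geometry(z2):
        raise ArgumentError("backgrounds must induce the same density grid geometry")
    d_obs = schoener_D(z1, z2)

    null = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(len(background2), size=len(occ2))
        pseudo = background2[idx]
        null[r] = schoener_D(z1, density_grid(pseudo, background2, R=R))
    p = _two_sided_p(int(np.sum(null >= d_obs)), reps)
    return d_obs, null, p
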