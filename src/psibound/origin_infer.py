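"""Expansion-origin inference from clines in psi or pairwise diversity.

Two estimators are provided:

* **TDoA** (time difference of arrival): a grid search over candidate origins.
  For a candidate point g and every unordered population pair (i, j) the
  predictor is the distance difference ``dd_ij(g) = d(g, j) - d(g, i)``; an
  ordinary least-squares regression of ``psi_ij`` on ``dd_ij(g)`` is fitted and
  the origin estimate is the grid point with the strongest qualifying
  coefficient of determination (positive slope for psi; for pairwise
  heterozygosity differences the qualifying relationship is the mirror-image
  cline, see :func:`tdoa_surface`).  Because the pairwise observations are not
  independent, the regression p-values are wildly anti-conservative; they are
  reported for description only (``p_descriptive``).

* **non-TDoA**: one regression per focal population of ``psi(focal, other)``
  on ``d(focal, other)`` over the remaining P-1 populations, with standard OLS
  degrees of freedom.  The strongest positive r-squared over focal populations
  is the effect size tau used by the boundary-effect model.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "OriginSurface",
    "FocalScan",
    "pairwise_distances",
    "tdoa_surface",
    "non_tdoa_scan",
    "rmse_origin",
    "delta_het_matrix",
]

_EARTH_RADIUS_KM = 6371.0


def _haversine(a, b):
    """Great-circle distance in km between (lon, lat) arrays (degrees)."""
    lon1, lat1 = np.radians(a[..., 0]), np.radians(a[..., 1])
    lon2, lat2 = np.radians(b[..., 0]), np.radians(b[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def pairwise_distances(points_a, points_b, lonlat=False):
    """Distance matrix between two coordinate sets ((n,2) and (m,2))."""
    a = np.asarray(points_a, float)[:, None, :]
    b = np.asarray(points_b, float)[None, :, :]
    if lonlat:
        return _haversine(a, b)
    return np.sqrt(((a - b) ** 2).sum(-1))


@dataclasses.dataclass
class OriginSurface:
    """Per-grid-point TDoA regression fits and the best-origin record.

    ``p_descriptive`` carries the per-grid-point regression p-values; they are
    anti-conservative by construction (non-independent pairwise observations)
    and must not be used as test results.
    """

    grid: np.ndarray            # (G, 2) candidate origins
    r2: np.ndarray
    slope: np.ndarray
    p_descriptive: np.ndarray
    best_index: int
    no_cline: bool
    on_padding_boundary: bool
    statistic: str

    @property
    def best_origin(self) -> np.ndarray:
        return self.grid[self.best_index]

    @property
    def tau_tdoa(self) -> float:
        return 0.0 if self.no_cline else float(self.r2[self.best_index])


@dataclasses.dataclass
class FocalScan:
    """Per-focal-population regressions of a clinal statistic on distance."""

    populations: list
    r2: np.ndarray
    slope: np.ndarray
    p: np.ndarray
    best_index: int
    no_cline: bool
    statistic: str

    @property
    def best_pop(self):
        return self.populations[self.best_index]

    @property
    def tau_non_tdoa(self) -> float:
        return 0.0 if self.no_cline else float(self.r2[self.best_index])


def _default_grid(coords, G, pad):
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    lo = lo - pad * span
    hi = hi + pad * span
    gx = np.linspace(lo[0], hi[0], G)
    gy = np.linspace(lo[1], hi[1], G)
    xx, yy = np.meshgrid(gx, gy)
    return np.column_stack([xx.ravel(), yy.ravel()])


def _batched_regression(X, y):
    """OLS of y on each row of X. Returns (slope, r2, p) arrays."""
    n = y.size
    ym = y - y.mean()
    Xm = X - X.mean(axis=1, keepdims=True)
    sxx = (Xm ** 2).sum(axis=1)
    sxy = Xm @ ym
    syy = float(ym @ ym)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = sxy / sxx
        r2 = np.where((sxx > 0) & (syy > 0), sxy ** 2 / (sxx * syy), 0.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = np.sqrt(np.maximum(r2, 0) * df / np.maximum(1 - r2, 1e-300))
    p = 2 * stats.t.sf(np.abs(tstat), df)
    return slope, r2, p


def tdoa_surface(statistic_matrix, coords, G=100, statistic="psi", pad=0.2,
                 grid=None, lonlat=False, tie_tol=1e-12) -> OriginSurface:
    """TDoA grid search for the expansion origin.

    Parameters
    ----------
    statistic_matrix:
        Antisymmetric pairwise matrix; psi, or the heterozygosity difference
        ``delta_ij = H_i - H_j`` from :func:`delta_het_matrix`.
    coords:
        (P, 2) population coordinates (same order as the matrix).
    G:
        Grid resolution per axis (default 100 x 100 over the sampling bounding
        box padded by 20% per side).
    statistic:
        ``"psi"`` -- the origin maximizes r2 among grid points where psi
        increases with the distance difference (positive slope).
        ``"het"`` -- with ``delta_ij = H_i - H_j``, diversity decays away from
        the origin, so the qualifying regression of ``H_j - H_i`` on the
        distance difference has negative slope; equivalently a positive slope
        on ``delta_ij``.  Both orientations select the same grid point.
    grid:
        Optional explicit (G, 2) candidate array; ``"populations"`` restricts
        candidates to the sampled coordinates (the stepping-stone convention).

    Ties within ``tie_tol`` of the maximal r2 are broken deterministically in
    favor of the candidate closest to the centroid of the sampled populations.
    """
    coords = np.asarray(coords, float)
    P = coords.shape[0]
    if P < 3:
        raise ValueError("at least 3 populations required")
    M = np.asarray(statistic_matrix, float)
    iu, ju = np.triu_indices(P, 1)
    y = M[iu, ju]

    if isinstance(grid, str) and grid == "populations":
        gpts = coords.copy()
        padded = np.zeros(len(gpts), bool)
    elif grid is not None:
        gpts = np.asarray(grid, float)
        padded = np.zeros(len(gpts), bool)
    else:
        gpts = _default_grid(coords, G, pad)
        lo = gpts.min(axis=0)
        hi = gpts.max(axis=0)
        padded = ((gpts[:, 0] <= lo[0]) | (gpts[:, 0] >= hi[0])
                  | (gpts[:, 1] <= lo[1]) | (gpts[:, 1] >= hi[1]))

    D = pairwise_distances(gpts, coords, lonlat=lonlat)  # (G, P)
    X = D[:, ju] - D[:, iu]  # dd_ij(g) = d(g, j) - d(g, i)
    slope, r2, p = _batched_regression(X, y)

    qualify = slope > 0
    no_cline = not bool(qualify.any()) or not np.isfinite(y).all() or np.allclose(y, 0)
    if no_cline and np.allclose(y, 0):
        best = 0
    else:
        score = np.where(qualify, r2, -np.inf)
        rmax = score.max()
        if not np.isfinite(rmax):
            best = 0
            no_cline = True
        else:
            cand = np.flatnonzero(score >= rmax - tie_tol)
            centroid = coords.mean(axis=0)
            dc = pairwise_distances(gpts[cand], centroid[None, :], lonlat=lonlat)[:, 0]
            best = int(cand[np.argmin(dc)])
    return OriginSurface(
        grid=gpts,
        r2=r2,
        slope=slope,
        p_descriptive=p,
        best_index=best,
        no_cline=no_cline,
        on_padding_boundary=bool(padded[best]),
        statistic=statistic,
    )


def non_tdoa_scan(statistic_matrix, coords, populations=None, statistic="psi",
                  lonlat=False) -> FocalScan:
    """Per-focal-population regression of the clinal statistic on distance.

    For psi, the focal population is a candidate origin when psi(focal, other)
    increases with distance (positive slope); for the heterozygosity
    difference, diversity decays away from the origin so ``H_other - H_focal``
    decreases with distance and the qualifying slope is negative.  tau is the
    strongest qualifying r-squared.
    """
    coords = np.asarray(coords, float)
    P = coords.shape[0]
    if P < 3:
        raise ValueError("at least 3 populations required")
    M = np.asarray(statistic_matrix, float)
    if populations is None:
        populations = list(range(P))
    r2 = np.zeros(P)
    slope = np.zeros(P)
    pvals = np.ones(P)
    D = pairwise_distances(coords, coords, lonlat=lonlat)
    for i in range(P):
        others = np.arange(P) != i
        y = M[i, others]
        if statistic == "het":
            y = -y  # H_other - H_focal decays with distance from the origin
        x = D[i, others]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            # degenerate regression (e.g. focal equidistant from all others)
            r2[i], slope[i], pvals[i] = 0.0, 0.0, 1.0
            continue
        res = stats.linregress(x, y)
        r2[i] = res.rvalue ** 2
        slope[i] = res.slope
        pvals[i] = res.pvalue
    qualify = slope > 0 if statistic == "psi" else slope < 0
    no_cline = not bool(qualify.any())
    if no_cline:
        best = 0
    else:
        score = np.where(qualify, r2, -np.inf)
        best = int(np.argmax(score))
    return FocalScan(
        populations=list(populations),
        r2=r2,
        slope=slope,
        p=pvals,
        best_index=best,
        no_cline=no_cline,
        statistic=statistic,
    )


def rmse_origin(estimates, truth) -> float:
    """Root mean squared Euclidean distance of origin estimates to the truth."""
    est = np.atleast_2d(np.asarray(estimates, float))
    t = np.asarray(truth, float)
    d2 = ((est - t) ** 2).sum(axis=1)
    return float(np.sqrt(d2.mean()))


def delta_het_matrix(div) -> np.ndarray:
    """Antisymmetric pairwise diversity differences ``delta_ij = H_i - H_j``."""
    h = np.asarray(div.het if hasattr(div, "het") else div, float)
    return h[:, None] - h[None, :]
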