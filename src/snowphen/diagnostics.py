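"""Observer-bias and residual spatial-autocorrelation diagnostics.

Citizen-science effort is heterogeneous over date and elevation; if
observers concentrated exactly where and when broods are, apparent
phenology would partly mirror observer behaviour.  The check compares
bivariate Gaussian kernel densities of observer activity and of hatching
events over the (date, elevation) plane: broods well inside the observer
distribution argue for a biological rather than observational signal.

Spatial structure left in model residuals is screened with an empirical
semivariogram, gamma(h) = mean over pairs at distance h of
(r_i - r_j)^2 / 2; a flat profile indicates no residual autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import gaussian_kde

__all__ = ["KdeSurface", "Semivariogram", "observer_vs_brood_kde",
           "residual_semivariogram"]


@dataclass
class KdeSurface:
    x_grid: np.ndarray       # date axis
    y_grid: np.ndarray       # elevation axis
    density: np.ndarray      # (ny, nx), integrates to ~1 over the grid
    hdr_threshold: float     # density level enclosing 95% of the mass

    @property
    def hdr_mask(self) -> np.ndarray:
        return self.density >= self.hdr_threshold

    def mass(self, mask: np.ndarray | None = None) -> float:
        dx = self.x_grid[1] - self.x_grid[0]
        dy = self.y_grid[1] - self.y_grid[0]
        d = self.density if mask is None else self.density * mask
        return float(d.sum() * dx * dy)


def _kde_surface(points: np.ndarray, x_grid: np.ndarray, y_grid: np.ndarray,
                 mass_level: float = 0.95) -> KdeSurface:
    kde = gaussian_kde(points.T)   # Scott's rule bandwidth
    xx, yy = np.meshgrid(x_grid, y_grid)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    dx, dy = x_grid[1] - x_grid[0], y_grid[1] - y_grid[0]
    dens = dens / (dens.sum() * dx * dy)
    # highest-density region: lowest level whose super-level set holds 95%
    order = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(order) * dx * dy
    k = int(np.searchsorted(cum, mass_level))
    thr = float(order[min(k, len(order) - 1)])
    return KdeSurface(x_grid, y_grid, dens, thr)


def observer_vs_brood_kde(observer_points: np.ndarray,
                          brood_points: np.ndarray,
                          grid_size: int = 128,
                          mass_level: float = 0.95,
                          ) -> tuple[KdeSurface, KdeSurface, float]:
    """Compare observer and brood distributions over (date, elevation).

    Both point sets are (n, 2) arrays of (day-of-year, elevation).  Returns
    the two KDE surfaces on a shared grid and the containment fraction:
    the share of the brood distribution's 95% highest-density mass that
    lies inside the observer distribution's 95% region.  A fraction near 1
    means observers covered the broods' space-time footprint.
    """
    obs = np.asarray(observer_points, dtype=float)
    brd = np.asarray(brood_points, dtype=float)
    for name, pts in (("observer", obs), ("brood", brd)):
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 10:
            raise ValueError(f"{name} points must be (n>=10, 2)")
        if np.allclose(pts.std(axis=0), 0):
            raise ValueError(f"{name} points are degenerate")
    allp = np.vstack([obs, brd])
    span = allp.max(axis=0) - allp.min(axis=0)
    lo = allp.min(axis=0) - 0.15 * span
    hi = allp.max(axis=0) + 0.15 * span
    x = np.linspace(lo[0], hi[0], grid_size)
    y = np.linspace(lo[1], hi[1], grid_size)
    s_obs = _kde_surface(obs, x, y, mass_level)
    s_brd = _kde_surface(brd, x, y, mass_level)
    inside = s_brd.mass(s_brd.hdr_mask & s_obs.hdr_mask)
    total = s_brd.mass(s_brd.hdr_mask)
    return s_obs, s_brd, float(inside / total) if total > 0 else float("nan")


@dataclass
class Semivariogram:
    midpoints: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray

    @property
    def sill(self) -> float:
        return float(np.average(self.gamma[self.counts > 0],
                                weights=self.counts[self.counts > 0]))


def residual_semivariogram(residuals: np.ndarray, coords: np.ndarray,
                           n_classes: int = 10,
                           max_dist: float | None = None) -> Semivariogram:
    """Empirical semivariogram of model residuals.

    Distance classes are equal-width bins up to half the maximum pairwise
    distance by default (standard geostatistical practice, avoiding the
    sparse far tail).  Pairs beyond the last class are dropped.
    """
    r = np.asarray(residuals, dtype=float)
    xy = np.asarray(coords, dtype=float)
    if len(r) < 2:
        raise ValueError("need at least 2 residuals")
    if len(r) != len(xy):
        raise ValueError("residuals and coordinates differ in length")
    d = pdist(xy)
    sv = pdist(r[:, None], metric="sqeuclidean") / 2.0
    if max_dist is None:
        max_dist = float(d.max()) / 2.0 if d.max() > 0 else 1.0
    edges = np.linspace(0, max_dist, n_classes + 1)
    idx = np.digitize(d, edges[1:-1])
    keep = d <= max_dist
    gamma = np.zeros(n_classes)
    counts = np.zeros(n_classes, dtype=int)
    for k in range(n_classes):
        sel = keep & (idx == k)
        counts[k] = int(sel.sum())
        gamma[k] = float(sv[sel].mean()) if counts[k] else np.nan
    mids = 0.5 * (edges[:-1] + edges[1:])
    return Semivariogram(mids, gamma, counts)
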