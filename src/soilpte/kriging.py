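"""Empirical semivariograms, spherical model fitting and ordinary kriging.

The semivariogram gamma(h) is half the expected squared difference of the
field at separation h.  The spherical model

    gamma(h) = nugget + psill * (1.5 h/a - 0.5 (h/a)^3)   for 0 < h <= a
    gamma(h) = sill                                       for h > a
    gamma(0) = 0

is fit to the binned empirical semivariogram by pair-count-weighted least
squares.  Ordinary kriging solves the (n+1) linear system with a Lagrange
multiplier enforcing that the weights sum to one (unbiasedness), using the
full data neighbourhood — appropriate at survey sizes of a few hundred
points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

__all__ = [
    "VariogramModel", "KrigedSurface", "empirical_semivariogram",
    "spherical_gamma", "fit_spherical_model", "krige_point", "krige_grid",
    "write_esri_ascii",
]


class KrigingError(ValueError):
    pass


@dataclass(frozen=True)
class VariogramModel:
    """Spherical semivariogram parameters (variance units / metres)."""

    nugget: float
    sill: float
    range_a: float
    model: str = "spherical"

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.sill < self.nugget:
            raise KrigingError("need 0 <= nugget <= sill")
        if self.range_a <= 0:
            raise KrigingError("range must be positive")
        if self.model != "spherical":
            raise KrigingError(f"unsupported model {self.model!r}")

    @property
    def partial_sill(self) -> float:
        return self.sill - self.nugget


@dataclass
class KrigedSurface:
    """Gridded ordinary-kriging predictions with per-cell variance."""

    x: np.ndarray          # grid x coordinates (nx,)
    y: np.ndarray          # grid y coordinates (ny,)
    predictions: np.ndarray  # (ny, nx)
    variance: np.ndarray     # (ny, nx)
    model: VariogramModel


def empirical_semivariogram(points, n_lags: int = 12, max_dist: float | None = None):
    """Binned empirical semivariogram.

    Parameters
    ----------
    points:
        Sequence or array of (x, y, z) triples.
    n_lags, max_dist:
        Number of equal-width distance bins up to ``max_dist`` (default:
        half the maximum pairwise distance, the common working rule).

    Returns
    -------
    (lag_centers, gamma_hat, counts): arrays of length ``n_lags``; bins with
    no pairs carry NaN in ``gamma_hat`` and zero count.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise KrigingError("need at least two (x, y, z) points")
    xy, z = pts[:, :2], pts[:, 2]
    d = cdist(xy, xy)
    iu = np.triu_indices(len(z), k=1)
    dist = d[iu]
    sq = (z[iu[0]] - z[iu[1]]) ** 2
    if max_dist is None:
        max_dist = float(dist.max()) / 2.0
    if max_dist <= 0:
        raise KrigingError("max_dist must be positive")
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    gamma = np.full(n_lags, np.nan)
    counts = np.zeros(n_lags, dtype=int)
    which = np.digitize(dist, edges[1:], right=True)
    for b in range(n_lags):
        sel = (which == b) & (dist <= max_dist)
        counts[b] = int(sel.sum())
        if counts[b]:
            gamma[b] = sq[sel].sum() / (2.0 * counts[b])
    return centers, gamma, counts


def spherical_gamma(h, model: VariogramModel):
    """Evaluate the spherical semivariogram at lag(s) ``h`` (>= 0)."""
    h = np.asarray(h, float)
    if np.any(h < 0):
        raise KrigingError("negative lag distance")
    r = np.clip(h / model.range_a, 0.0, 1.0)
    g = model.nugget + model.partial_sill * (1.5 * r - 0.5 * r**3)
    g = np.where(h > model.range_a, model.sill, g)
    g = np.where(h == 0.0, 0.0, g)
    return g if g.ndim else float(g)


def fit_spherical_model(lags, gamma_hat, counts) -> VariogramModel:
    """Pair-count-weighted least-squares fit of the spherical model.

    Deterministic multi-start over a range grid guards against the local
    minima of the range parameter.
    """
    lags = np.asarray(lags, float)
    gamma_hat = np.asarray(gamma_hat, float)
    counts = np.asarray(counts, float)
    ok = np.isfinite(gamma_hat) & (counts > 0)
    if ok.sum() < 3:
        raise KrigingError("need at least three occupied lag bins")
    h, g, w = lags[ok], gamma_hat[ok], np.sqrt(counts[ok])
    if np.allclose(g, 0.0):
        return VariogramModel(0.0, 0.0, float(h.max()))

    gscale = max(float(g.max()), 1e-30)
    # tiny partial-sill penalty resolves the flat-input degeneracy (a flat
    # semivariogram is otherwise fit equally well by any nugget/sill split
    # once the range drops below the first lag) in favour of pure nugget
    penalty = 1e-4 * np.sqrt(counts[ok].sum()) / gscale

    def resid(theta):
        nugget, psill, rng = theta
        m = VariogramModel(0.0, psill if psill > 0 else 0.0, max(rng, 1e-9))
        base = np.asarray(spherical_gamma(h, m))
        return np.append(w * (nugget + base - g), penalty * psill)

    gmax, hmax = float(g.max()), float(h.max())
    best = None
    for r0 in np.linspace(hmax / 10, 1.5 * hmax, 8):
        res = least_squares(
            resid, x0=[0.1 * gmax, 0.9 * gmax, r0],
            bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, 10 * hmax]),
            method="trf",
        )
        if best is None or res.cost < best.cost - 1e-12:
            best = res
    nugget, psill, rng = best.x
    return VariogramModel(float(nugget), float(nugget + psill), float(rng))


def _kriging_system(coords: np.ndarray, model: VariogramModel) -> np.ndarray:
    n = len(coords)
    d = cdist(coords, coords)
    if model.nugget == 0.0:
        iu = np.triu_indices(n, k=1)
        dup = np.nonzero(d[iu] == 0.0)[0]
        if dup.size:
            i, j = iu[0][dup[0]], iu[1][dup[0]]
            raise KrigingError(
                f"duplicate coordinates at samples {i} and {j} with zero "
                "nugget make the kriging system singular"
            )
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = np.asarray(spherical_gamma(d, model))
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    return A


def krige_point(x0, points, model: VariogramModel,
                _factor=None) -> tuple[float, float, np.ndarray]:
    """Ordinary-kriging prediction at one location.

    Returns ``(prediction, kriging_variance, weights)``; weights sum to one
    by construction of the constrained system.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 1:
        raise KrigingError("need at least one (x, y, z) point")
    coords, z = pts[:, :2], pts[:, 2]
    n = len(z)
    if n == 1:
        return float(z[0]), float(spherical_gamma(
            float(np.hypot(*(np.asarray(x0, float) - coords[0]))), model)) * 2 - float(
            spherical_gamma(0.0, model)), np.array([1.0])
    b = np.empty(n + 1)
    b[:n] = np.asarray(spherical_gamma(
        np.linalg.norm(coords - np.asarray(x0, float), axis=1), model))
    b[n] = 1.0
    if _factor is None:
        A = _kriging_system(coords, model)
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise KrigingError(f"singular kriging system: {exc}") from exc
    else:
        from scipy.linalg import lu_solve
        sol = lu_solve(_factor, b)
    lam, mu = sol[:n], sol[n]
    zhat = float(lam @ z)
    var = float(lam @ b[:n] + mu)
    return zhat, max(var, 0.0), lam


def krige_grid(points, model: VariogramModel, grid_x, grid_y,
               jitter_duplicates: bool = True) -> KrigedSurface:
    """Ordinary kriging of scattered points onto a rectangular grid.

    The data covariance system is factorised once and reused per cell.
    Duplicate coordinates under a zero nugget are jittered by 1e-6 of the
    range (with a warning) so the system stays solvable.
    """
    from scipy.linalg import lu_factor, lu_solve

    pts = np.asarray(points, float).copy()
    gx, gy = np.asarray(grid_x, float), np.asarray(grid_y, float)
    coords, z = pts[:, :2], pts[:, 2]
    if model.nugget == 0.0:
        d = cdist(coords, coords)
        np.fill_diagonal(d, np.inf)
        if (d == 0.0).any():
            warnings.warn("duplicate coordinates with zero nugget; jittering "
                          "by 1e-6 of the range", stacklevel=2)
            rng = np.random.default_rng(0)
            dup = np.unique(np.nonzero(np.triu(d == 0.0))[1])
            coords[dup] += rng.normal(0.0, 1e-6 * model.range_a, (dup.size, 2))
            pts[:, :2] = coords
    A = _kriging_system(coords, model)
    factor = lu_factor(A)
    n = len(z)
    pred = np.empty((gy.size, gx.size))
    var = np.empty_like(pred)
    for iy, yv in enumerate(gy):
        for ix, xv in enumerate(gx):
            b = np.empty(n + 1)
            b[:n] = np.asarray(spherical_gamma(
                np.linalg.norm(coords - np.array([xv, yv]), axis=1), model))
            b[n] = 1.0
            sol = lu_solve(factor, b)
            lam, mu = sol[:n], sol[n]
            assert abs(lam.sum() - 1.0) < 1e-9, "kriging weights must sum to 1"
            pred[iy, ix] = lam @ z
            var[iy, ix] = max(float(lam @ b[:n] + mu), 0.0)
    return KrigedSurface(gx, gy, pred, var, model)


def write_esri_ascii(surface: KrigedSurface, path, nodata: float = -9999.0) -> None:
    """Write the prediction grid as an ESRI ASCII raster (requires a
    uniform cell size in both directions)."""
    gx, gy = surface.x, surface.y
    dx = np.diff(gx)
    dy = np.diff(gy)
    if len(gx) > 1 and (not np.allclose(dx, dx[0]) or
                        (len(gy) > 1 and not np.allclose(dy, dy[0], atol=1e-9))):
        raise KrigingError("ESRI ASCII export requires a regular grid")
    cell = float(dx[0]) if len(gx) > 1 else (float(dy[0]) if len(gy) > 1 else 1.0)
    with open(path, "w") as fh:
        fh.write(f"ncols {len(gx)}\n")
        fh.write(f"nrows {len(gy)}\n")
        fh.write(f"xllcenter {gx[0]:.6f}\n")
        fh.write(f"yllcenter {gy[0]:.6f}\n")
        fh.write(f"cellsize {cell:.6f}\n")
        fh.write(f"nodata_value {nodata:g}\n")
        for row in surface.predictions[::-1]:  # north-up raster order
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")
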