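"""Geostatistical interpolation and pollution-area delineation.

Provides inverse-distance weighting, empirical-variogram fitting with
exponential/spherical models, ordinary kriging (BLUP with the unbiasedness
constraint), and an empirical-Bayesian-style kriging variant that accounts
for variogram-estimation error: the fitted variogram is used to simulate
replicate data at the observation locations, each replicate is refitted,
and the resulting variogram ensemble is weighted by the Gaussian
likelihood of the observed data under each member's covariance. Predicted
surfaces are rasterized over the convex hull of the sites (buffered by the
median nearest-neighbour distance) and compared with per-site statistics
to delineate contaminated area fractions.

The exponential variogram here is gamma(h) = nugget + (sill-nugget) *
(1 - exp(-h / range)), i.e. ``range`` is the e-folding correlation length,
matching the covariance used by the synthetic generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from scipy.optimize import curve_fit
from shapely.geometry import MultiPoint


@dataclass(frozen=True)
class VariogramModel:
    """Fitted semivariogram: gamma(h) with nugget/sill/range parameters."""

    model: str  # "exponential" or "spherical"
    nugget: float
    sill: float
    range_: float

    def __post_init__(self) -> None:
        if self.model not in {"exponential", "spherical"}:
            raise ValueError(f"unknown variogram model {self.model!r}")
        if not (self.sill >= self.nugget >= 0):
            raise ValueError("need sill >= nugget >= 0")
        if self.range_ <= 0:
            raise ValueError("range must be > 0")

    def gamma(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        psill = self.sill - self.nugget
        if self.model == "exponential":
            struct = 1.0 - np.exp(-h / self.range_)
        else:  # spherical
            hr = np.clip(h / self.range_, 0.0, 1.0)
            struct = 1.5 * hr - 0.5 * hr ** 3
        g = self.nugget + psill * struct
        return np.where(h == 0.0, 0.0, g)

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """C(h) = sill - gamma(h); C(0) = sill (nugget included at the origin)."""
        return self.sill - self.gamma(h)


@dataclass
class Grid:
    """Regular raster geometry: lower-left origin, square cells."""

    x0: float
    y0: float
    cell: float
    ncols: int
    nrows: int

    @property
    def xs(self) -> np.ndarray:
        return self.x0 + self.cell * (np.arange(self.ncols) + 0.5)

    @property
    def ys(self) -> np.ndarray:
        return self.y0 + self.cell * (np.arange(self.nrows) + 0.5)

    def centers(self) -> np.ndarray:
        """(nrows*ncols) x 2 cell-center coordinates, row-major from the south."""
        xx, yy = np.meshgrid(self.xs, self.ys)
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class RasterSurface:
    """Interpolated grid with a study-area mask and area-fraction helpers."""

    grid: Grid
    values: np.ndarray  # nrows x ncols
    mask: np.ndarray  # nrows x ncols booleans; True = inside study area

    def __post_init__(self) -> None:
        if self.values.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError("values shape does not match grid")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match grid")

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]

    def area_fraction(self, rule) -> float:
        """Percent of in-mask cells where ``rule(value)`` is True."""
        inside = self.masked_values()
        if inside.size == 0:
            raise ValueError("empty mask: no cells inside the study area")
        return 100.0 * float(np.count_nonzero(rule(inside))) / inside.size

    def write_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        """ESRI ASCII grid; masked-out cells written as NODATA."""
        out = np.where(self.mask, self.values, nodata)
        header = (f"ncols {self.grid.ncols}\nnrows {self.grid.nrows}\n"
                  f"xllcorner {self.grid.x0}\nyllcorner {self.grid.y0}\n"
                  f"cellsize {self.grid.cell}\nNODATA_value {nodata}\n")
        body = "\n".join(" ".join(f"{v:.6g}" for v in row)
                         for row in out[::-1])  # ASCII grids run north->south
        Path(path).write_text(header + body + "\n")


def make_grid(coords: np.ndarray, ncells: int = 100,
              pad_fraction: float = 0.05) -> Grid:
    """Square-cell grid covering the bounding box of the sites (plus padding)."""
    coords = np.asarray(coords, dtype=float)
    xmin, ymin = coords.min(axis=0)
    xmax, ymax = coords.max(axis=0)
    span = max(xmax - xmin, ymax - ymin)
    pad = pad_fraction * span
    xmin, ymin, xmax, ymax = xmin - pad, ymin - pad, xmax + pad, ymax + pad
    cell = max(xmax - xmin, ymax - ymin) / ncells
    ncols = int(np.ceil((xmax - xmin) / cell))
    nrows = int(np.ceil((ymax - ymin) / cell))
    return Grid(x0=xmin, y0=ymin, cell=cell, ncols=ncols, nrows=nrows)


def study_mask(coords: np.ndarray, grid: Grid) -> np.ndarray:
    """Convex hull of sites buffered by median nearest-neighbour distance."""
    coords = np.asarray(coords, dtype=float)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    buffer = float(np.median(d.min(axis=1)))
    hull = MultiPoint([tuple(c) for c in coords]).convex_hull.buffer(buffer)
    centers = grid.centers()
    inside = shapely.contains_xy(hull, centers[:, 0], centers[:, 1])
    return inside.reshape(grid.nrows, grid.ncols)


def _surface(grid, pred, mask):
    return RasterSurface(grid=grid, values=pred.reshape(grid.nrows, grid.ncols),
                         mask=mask)


def idw(coords: np.ndarray, values: np.ndarray, grid: Grid,
        power: float = 2.0, mask: np.ndarray | None = None) -> RasterSurface:
    """Inverse-distance-weighted surface; exact at coincident cell centers."""
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("idw requires at least one site")
    if power <= 0:
        raise ValueError("power must be > 0")
    if mask is None:
        mask = study_mask(coords, grid)
    centers = grid.centers()
    d = np.linalg.norm(centers[:, None, :] - coords[None, :, :], axis=-1)
    pred = np.empty(centers.shape[0])
    coincident = d < 1e-9
    hit = coincident.any(axis=1)
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[hit] = 0.0
    pred[~hit] = (w[~hit] @ values) / w[~hit].sum(axis=1)
    if hit.any():
        pred[hit] = values[np.argmax(coincident[hit], axis=1)]
    return _surface(grid, pred, mask)


def empirical_variogram(coords: np.ndarray, values: np.ndarray,
                        n_bins: int = 12) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned empirical semivariance: (bin centers, gamma, pair counts)."""
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    iu = np.triu_indices(coords.shape[0], k=1)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)[iu]
    sq = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    if d.size < 10:
        raise ValueError("need at least 10 site pairs for a variogram")
    hmax = 0.5 * d.max()
    edges = np.linspace(0.0, hmax, n_bins + 1)
    centers, gamma, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d > lo) & (d <= hi)
        if sel.sum() == 0:
            continue
        centers.append(d[sel].mean())
        gamma.append(sq[sel].mean())
        counts.append(sel.sum())
    return np.array(centers), np.array(gamma), np.array(counts)


def fit_variogram(coords: np.ndarray, values: np.ndarray,
                  model: str = "exponential", n_bins: int = 12) -> VariogramModel:
    """Weighted least-squares fit of a variogram model to the empirical cloud.

    Bins are weighted by pair counts. Collinear site geometries only get a
    warning — the fit proceeds on whatever distance support exists. A
    constant field yields sill = nugget = 0.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    h, g, cnt = empirical_variogram(coords, values, n_bins)

    # collinearity check (degenerate geometry still fits, with a warning)
    c = coords - coords.mean(axis=0)
    sv = np.linalg.svd(c, compute_uv=False)
    if sv[0] > 0 and sv[-1] / sv[0] < 1e-10:
        warnings.warn("sites are (nearly) collinear; variogram fit may be poor")

    var = values.var()
    if var == 0.0 or np.all(g == 0.0):
        return VariogramModel(model=model, nugget=0.0, sill=0.0,
                              range_=max(h.max(), 1.0))

    def gfun(hh, nugget, psill, rng):
        return VariogramModel(model, nugget, nugget + psill, rng).gamma(hh)

    hmax = h.max()
    p0 = (0.1 * var, var, hmax / 3.0)
    bounds = ([0.0, 0.0, 1e-9 * hmax], [2.0 * var, 5.0 * var, 2.0 * hmax])
    # Cressie weights N(h)/gamma_model(h)^2, iteratively reweighted from a
    # pair-count-weighted first pass
    popt = p0
    try:
        for _ in range(3):
            gm = np.maximum(gfun(h, *popt), 1e-12 * max(var, 1.0))
            sigma = gm / np.sqrt(cnt)
            popt, _ = curve_fit(gfun, h, g, p0=popt, sigma=sigma,
                                bounds=bounds, maxfev=20000)
    except RuntimeError:
        warnings.warn("variogram fit did not converge; using moment estimates")
    nugget, psill, rng = popt
    return VariogramModel(model=model, nugget=float(nugget),
                          sill=float(nugget + psill), range_=float(rng))


def _dedupe(coords: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average values at duplicate locations (singular kriging systems)."""
    uniq, inv = np.unique(np.round(coords, 9), axis=0, return_inverse=True)
    if uniq.shape[0] == coords.shape[0]:
        return coords, values
    warnings.warn("duplicate site locations: averaging values")
    out = np.array([values[inv == k].mean() for k in range(uniq.shape[0])])
    return uniq, out


def ordinary_kriging(coords: np.ndarray, values: np.ndarray, grid: Grid,
                     vm: VariogramModel,
                     mask: np.ndarray | None = None) -> RasterSurface:
    """Ordinary-kriging surface (BLUP with the unbiasedness constraint).

    With zero nugget the predictor interpolates the data exactly; with a
    pure-nugget model every prediction collapses to the global mean. A
    zero-sill (constant-field) model short-circuits to the mean surface.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    coords, values = _dedupe(coords, values)
    if mask is None:
        mask = study_mask(coords, grid)
    centers = grid.centers()
    n = coords.shape[0]
    if vm.sill == 0.0:
        return _surface(grid, np.full(centers.shape[0], values.mean()), mask)

    d_data = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    K = np.empty((n + 1, n + 1))
    K[:n, :n] = vm.covariance(d_data)
    K[:n, n] = 1.0
    K[n, :n] = 1.0
    K[n, n] = 0.0
    # tiny diagonal jitter keeps near-singular systems solvable
    K[:n, :n] += 1e-10 * vm.sill * np.eye(n)

    d_pred = np.linalg.norm(centers[:, None, :] - coords[None, :, :], axis=-1)
    rhs = np.empty((n + 1, centers.shape[0]))
    rhs[:n] = vm.covariance(d_pred).T
    rhs[n] = 1.0
    w = np.linalg.solve(K, rhs)
    pred = w[:n].T @ values
    return _surface(grid, pred, mask)


def kriging_weights(coords: np.ndarray, vm: VariogramModel,
                    target: np.ndarray) -> np.ndarray:
    """Ordinary-kriging weights for a single target point (diagnostic aid)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    K = np.empty((n + 1, n + 1))
    K[:n, :n] = vm.covariance(d)
    K[:n, n] = 1.0
    K[n, :n] = 1.0
    K[n, n] = 0.0
    rhs = np.empty(n + 1)
    rhs[:n] = vm.covariance(np.linalg.norm(coords - np.asarray(target), axis=1))
    rhs[n] = 1.0
    return np.linalg.solve(K, rhs)[:n]


def _gaussian_loglik(values: np.ndarray, coords: np.ndarray,
                     vm: VariogramModel) -> float:
    """Profile Gaussian log-likelihood of the data under vm's covariance."""
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    C = vm.covariance(d) + 1e-8 * max(vm.sill, 1e-12) * np.eye(n)
    r = values - values.mean()
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return -np.inf
    alpha = np.linalg.solve(L, r)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return float(-0.5 * (alpha @ alpha) - 0.5 * logdet)


def ebk_style(coords: np.ndarray, values: np.ndarray, grid: Grid,
              K: int = 100, seed: int = 0, model: str = "exponential",
              mask: np.ndarray | None = None) -> RasterSurface:
    """Variogram-resampling kriging (empirical-Bayesian-style).

    Fit a base variogram; simulate K replicate datasets at the observation
    locations from its Gaussian process; refit each replicate; weight each
    member variogram by the likelihood of the *observed* data under it
    (normalized); predict as the weight-averaged ordinary-kriging surface.
    ``K = 1`` reduces exactly to ordinary kriging with the fitted model.
    """
    if K < 1:
        raise ValueError("ensemble size K must be >= 1")
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    coords, values = _dedupe(coords, values)
    if mask is None:
        mask = study_mask(coords, grid)
    vm0 = fit_variogram(coords, values, model=model)
    if K == 1 or vm0.sill == 0.0:
        return ordinary_kriging(coords, values, grid, vm0, mask=mask)

    rng = np.random.default_rng(seed)
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    C = vm0.covariance(d) + 1e-8 * max(vm0.sill, 1e-12) * np.eye(n)
    L = np.linalg.cholesky(C)

    members: list[VariogramModel] = []
    logliks: list[float] = []
    for _ in range(K):
        sim = values.mean() + L @ rng.standard_normal(n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vmk = fit_variogram(coords, sim, model=model)
        if vmk.sill == 0.0:
            continue
        members.append(vmk)
        logliks.append(_gaussian_loglik(values, coords, vmk))

    if not members:
        warnings.warn("all ensemble members degenerate; using base variogram")
        return ordinary_kriging(coords, values, grid, vm0, mask=mask)
    ll = np.array(logliks)
    w = np.exp(ll - ll.max())
    if not np.isfinite(w).any() or w.sum() == 0.0:
        warnings.warn("all ensemble weights vanished; using base variogram")
        return ordinary_kriging(coords, values, grid, vm0, mask=mask)
    w /= w.sum()

    acc = np.zeros((grid.nrows, grid.ncols))
    for wk, vmk in zip(w, members):
        if wk < 1e-12:
            continue
        acc += wk * ordinary_kriging(coords, values, grid, vmk, mask=mask).values
    acc /= w[w >= 1e-12].sum()
    return RasterSurface(grid=grid, values=acc, mask=mask)


def combined_surface(kriged: RasterSurface, idw_surface: RasterSurface
                     ) -> RasterSurface:
    """Unweighted cellwise mean of the kriging and IDW surfaces."""
    if kriged.values.shape != idw_surface.values.shape:
        raise ValueError("surfaces must share a grid")
    return RasterSurface(grid=kriged.grid,
                         values=0.5 * (kriged.values + idw_surface.values),
                         mask=kriged.mask & idw_surface.mask)


def detect_polluted_area(site_values: np.ndarray, surface: RasterSurface,
                         rule) -> tuple[float, float]:
    """(site_fraction %, area_fraction %) of the contamination rule.

    ``rule`` is a vectorized predicate on values (e.g. ``lambda v: v < 1``
    for a capacity index, or ``lambda v: v > Cb`` for concentrations).
    """
    site_values = np.asarray(site_values, dtype=float)
    if site_values.size == 0:
        raise ValueError("no site values")
    site_fraction = 100.0 * float(np.count_nonzero(rule(site_values))) / site_values.size
    return site_fraction, surface.area_fraction(rule)


def pollution_area_table(survey, references=None, config=None,
                         seed: int = 0):
    """Per-metal site vs combined-interpolation contaminated fractions.

    For each metal the per-site capacity index Pi is interpolated with both
    ordinary kriging (fitted exponential variogram) and IDW; the combined
    surface is their cellwise mean; a cell or site is contaminated when
    Pi falls below the configured threshold (default 1, i.e. concentration
    above background). A final row applies the integrated-Pi rule.
    Returns (DataFrame, dict of combined surfaces by metal).
    """
    import pandas as pd

    from .core import PipelineConfig, default_references
    from .indices import compute_index_table

    refs = references or default_references()
    cfg = config or PipelineConfig()
    coords = survey.coords
    grid = make_grid(coords, ncells=cfg.grid_ncells)
    mask = study_mask(coords, grid)
    long, per_site = compute_index_table(survey, refs, cfg)

    rows, surfaces = [], {}
    for m in survey.metals:
        pi = long.loc[long["metal"] == m].set_index("site") \
            .reindex(survey.site_ids)["pi"].to_numpy()
        vm = fit_variogram(coords, pi)
        ok = ordinary_kriging(coords, pi, grid, vm, mask=mask)
        iw = idw(coords, pi, grid, mask=mask)
        comb = combined_surface(ok, iw)
        thr = cfg.contamination_pi_threshold
        site_fr, area_fr = detect_polluted_area(pi, comb, lambda v: v < thr)
        rows.append({"metal": m, "site_pct": site_fr, "interp_pct": area_fr})
        surfaces[m] = comb

    ipi = per_site["integrated_pi"].to_numpy()
    vm = fit_variogram(coords, ipi)
    comb = combined_surface(ordinary_kriging(coords, ipi, grid, vm, mask=mask),
                            idw(coords, ipi, grid, mask=mask))
    thr = cfg.integrated_pi_threshold
    site_fr, area_fr = detect_polluted_area(ipi, comb, lambda v: v < thr)
    rows.append({"metal": "all", "site_pct": site_fr, "interp_pct": area_fr})
    surfaces["all"] = comb
    return pd.DataFrame(rows), surfaces
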