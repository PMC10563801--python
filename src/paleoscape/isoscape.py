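"""Era-binned kriged maps of δ15N, δ13C and molar C/N.

Workflow: compute the classical (Matheron) empirical semivariogram of the
per-site era means, fit a parametric variogram family by pair-count-
weighted least squares, and solve the ordinary (or universal, with
polynomial drift) kriging system on a regular grid.  The mapping family
can be selected by seeded hold-out cross-validation — a random 15% of
points each predicted leave-one-out from all remaining points — or forced
(e.g. spherical for every era, so cross-era map differences reflect the
data rather than the interpolator).

Variogram conventions: γ(h) = nugget + partial_sill·g(h/range) for h > 0
with γ(0) = 0 (the nugget is a discontinuity at the origin, so kriging
interpolates exactly at data points); the range is the *effective* range
for the exponential and Gaussian families (γ reaches ~95% of the sill).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial.distance import cdist, pdist, squareform
from shapely.geometry import MultiPoint, Point

from .core import CoreSample, CoreSite, EraBin

FAMILIES = (
    "spherical",
    "circular",
    "exponential",
    "gaussian",
    "linear_drift1",
    "linear_drift2",
)


class VariogramError(ValueError):
    pass


# ---------------------------------------------------------------------------
# variogram models


def _g_spherical(u: np.ndarray) -> np.ndarray:
    u = np.minimum(u, 1.0)
    return 1.5 * u - 0.5 * u**3


def _g_circular(u: np.ndarray) -> np.ndarray:
    u = np.minimum(u, 1.0)
    return 1.0 - (2.0 / math.pi) * (np.arccos(u) - u * np.sqrt(1.0 - u**2))


def _g_exponential(u: np.ndarray) -> np.ndarray:
    # effective range: ~95% of sill at u = 1
    return 1.0 - np.exp(-3.0 * u)


def _g_gaussian(u: np.ndarray) -> np.ndarray:
    return 1.0 - np.exp(-3.0 * u**2)


_STRUCTURES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "spherical": _g_spherical,
    "circular": _g_circular,
    "exponential": _g_exponential,
    "gaussian": _g_gaussian,
}


@dataclass(frozen=True)
class VariogramModel:
    """Fitted semivariogram: family, nugget, partial sill, range, drift order.

    The two linear-drift families use a *linear* variogram,
    γ(h) = nugget + slope·h (``partial_sill`` holds the slope per ``range_m``
    metres), with universal-kriging polynomial drift of order 1 or 2.
    """

    family: str
    nugget: float
    partial_sill: float
    range_m: float
    rss: float = math.nan
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise VariogramError(f"unknown family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise VariogramError("nugget and partial sill must be >= 0")
        if self.range_m <= 0:
            raise VariogramError("range must be positive")

    @property
    def drift_order(self) -> int:
        if self.family == "linear_drift1":
            return 1
        if self.family == "linear_drift2":
            return 2
        return 0

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def gamma(self, h: np.ndarray | float) -> np.ndarray:
        """Semivariance at lag h (γ(0) = 0 exactly; nugget jump for h > 0)."""
        h = np.asarray(h, dtype=float)
        if self.family.startswith("linear"):
            struct = self.partial_sill * (h / self.range_m)
        else:
            struct = self.partial_sill * _STRUCTURES[self.family](h / self.range_m)
        out = np.where(h > 0, self.nugget + struct, 0.0)
        return out


# ---------------------------------------------------------------------------
# empirical variogram


@dataclass(frozen=True)
class EmpiricalVariogram:
    centers: np.ndarray  # lag-bin centers, m
    semivariance: np.ndarray
    counts: np.ndarray  # pairs per bin
    max_lag: float
    bin_width: float


def empirical_variogram(
    points: np.ndarray,
    values: np.ndarray,
    n_bins: int = 12,
    max_lag: float | None = None,
) -> EmpiricalVariogram:
    """Classical Matheron estimator γ̂(h) = Σ (z_i − z_j)² / (2 N(h)) per lag bin.

    ``max_lag`` defaults to half the maximum pairwise distance.  Bins with
    no pairs are dropped.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 2:
        raise VariogramError("need at least 2 points")
    if not np.isfinite(values).all():
        raise VariogramError("values must be finite")
    d = pdist(points)
    if d.max() == 0:
        raise VariogramError("all points coincident; no valid lags")
    if max_lag is None:
        max_lag = 0.5 * float(d.max())
    dv = pdist(values[:, None]) ** 2  # (z_i - z_j)^2 per pair
    width = max_lag / n_bins
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.digitize(d, edges[1:-1])
    sel = d <= max_lag
    centers, gammas, counts = [], [], []
    for b in range(n_bins):
        m = sel & (which == b)
        c = int(m.sum())
        if c == 0:
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        gammas.append(float(dv[m].sum() / (2.0 * c)))
        counts.append(c)
    return EmpiricalVariogram(
        np.array(centers), np.array(gammas), np.array(counts), float(max_lag), width
    )


def fit_variogram(emp: EmpiricalVariogram, family: str) -> VariogramModel:
    """Weighted least squares fit of one family to an empirical variogram.

    Weights are pair counts; parameters are bounded (nugget, sill ≥ 0,
    range > 0).  If the optimizer fails the moment-based initial estimate
    is returned with a ``wls_failed`` flag.
    """
    if family not in FAMILIES:
        raise VariogramError(f"unknown family {family!r}")
    if len(emp.centers) < 3:
        raise VariogramError("need at least 3 non-empty lag bins")
    h, g, w = emp.centers, emp.semivariance, emp.counts.astype(float)

    g_max = float(g.max())
    if g_max == 0.0:  # constant field
        return VariogramModel(family, 0.0, 0.0, max(emp.max_lag, 1.0))

    nug0 = max(float(g[0]) - (float(g[1]) - float(g[0])) * 0.5, 0.0) \
        if len(g) > 1 else 0.0
    nug0 = min(nug0, 0.5 * g_max)
    psill0 = max(g_max - nug0, 1e-12)
    rng0 = 0.6 * emp.max_lag
    x0 = np.array([nug0, psill0, rng0])

    def model(params: np.ndarray) -> np.ndarray:
        m = VariogramModel(family, max(params[0], 0.0), max(params[1], 1e-15),
                           max(params[2], 1e-9))
        return m.gamma(h)

    def resid(params: np.ndarray) -> np.ndarray:
        return np.sqrt(w) * (model(params) - g)

    try:
        res = optimize.least_squares(
            resid,
            x0,
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, 4.0 * emp.max_lag]),
            max_nfev=2000,
        )
        if not res.success:
            raise RuntimeError(res.message)
        nug, psill, rng = res.x
        rss = float(np.sum((model(res.x) - g) ** 2))
        return VariogramModel(family, float(nug), float(max(psill, 0.0)),
                              float(rng), rss=rss)
    except Exception:
        rss = float(np.sum((model(x0) - g) ** 2))
        return VariogramModel(family, nug0, psill0, rng0, rss=rss,
                              flags=("wls_failed_moment_fallback",))


# ---------------------------------------------------------------------------
# kriging


def _drift_basis(points: np.ndarray, order: int) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    cols = [np.ones(len(points))]
    if order >= 1:
        cols += [x, y]
    if order >= 2:
        cols += [x * y, x**2, y**2]
    return np.column_stack(cols)


def average_duplicates(
    points: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Average values at duplicate coordinates (exact ties)."""
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    uniq, inv = np.unique(points, axis=0, return_inverse=True)
    if len(uniq) == len(points):
        return points, values
    sums = np.zeros(len(uniq))
    cnts = np.zeros(len(uniq))
    np.add.at(sums, inv, values)
    np.add.at(cnts, inv, 1.0)
    return uniq, sums / cnts


def krige(
    points: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    targets: np.ndarray,
    return_weights: bool = False,
):
    """Solve the (universal) kriging system for each target point.

    Returns (predictions, variances) — and the weight matrix when
    ``return_weights`` — where the weights minimize prediction variance
    subject to the unbiasedness constraints (weights sum to 1 for ordinary
    kriging; polynomial drift constraints for drift orders 1–2).
    Duplicate data coordinates are averaged before solving.
    """
    points, values = average_duplicates(points, values)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n = len(points)
    if model.nugget == 0 and model.partial_sill == 0:
        # degenerate (constant-field) model: every unbiased weighting is
        # optimal; predict the mean with zero kriging variance
        m = len(targets)
        preds = np.full(m, float(np.mean(values)))
        if return_weights:
            return preds, np.zeros(m), np.full((m, n), 1.0 / n)
        return preds, np.zeros(m)
    order = model.drift_order
    f = _drift_basis(points, order)
    p = f.shape[1]
    if n < p + 1:
        raise VariogramError(f"need >= {p + 1} points for drift order {order}")

    gamma_mat = model.gamma(squareform(pdist(points)))
    np.fill_diagonal(gamma_mat, 0.0)
    a = np.zeros((n + p, n + p))
    a[:n, :n] = gamma_mat
    a[:n, n:] = f
    a[n:, :n] = f.T
    try:
        lu = lu_factor(a)
    except Exception as exc:  # singular even after duplicate averaging
        raise VariogramError(f"singular kriging system: {exc}") from exc

    g0 = model.gamma(cdist(targets, points))  # (m, n)
    f0 = _drift_basis(targets, order)  # (m, p)
    rhs = np.hstack([g0, f0]).T  # (n+p, m)
    sol = lu_solve(lu, rhs)  # (n+p, m)
    w = sol[:n, :]  # weights
    mu = sol[n:, :]  # Lagrange multipliers
    preds = w.T @ values
    variances = np.einsum("nm,mn->m", w, g0) + np.einsum("pm,mp->m", mu, f0)
    variances = np.where(variances < 0, 0.0, variances)  # clip numerical noise
    if return_weights:
        return preds, variances, w.T
    return preds, variances


# ---------------------------------------------------------------------------
# family selection by seeded hold-out cross-validation


@dataclass
class SelectionResult:
    best_family: str
    rmse: dict[str, float]  # nan for families that failed to fit
    holdout_idx: np.ndarray
    flags: dict = field(default_factory=dict)


def select_variogram(
    points: np.ndarray,
    values: np.ndarray,
    families: Sequence[str] = FAMILIES,
    holdout_fraction: float = 0.15,
    seed: int = 0,
    n_bins: int = 12,
) -> SelectionResult:
    """Choose the variogram family with the smallest hold-out RMSE.

    A seeded random ``holdout_fraction`` subset of the points is drawn
    once; each held-out point is predicted leave-one-out from *all* other
    points under each candidate family (whose parameters are fitted on
    the retained points only).  Ties resolve by the fixed family order
    (spherical first).
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(points)
    n_hold = max(int(round(holdout_fraction * n)), 2)
    if n_hold >= n - 2:
        raise VariogramError("too few points for hold-out selection")
    rng = np.random.default_rng(seed)
    holdout = np.sort(rng.choice(n, size=n_hold, replace=False))
    retained = np.setdiff1d(np.arange(n), holdout)

    rmse: dict[str, float] = {}
    flags: dict = {}
    emp = empirical_variogram(points[retained], values[retained], n_bins=n_bins)
    for fam in families:
        try:
            model = fit_variogram(emp, fam)
            errs = []
            for i in holdout:
                rest = np.arange(n) != i
                pred, _ = krige(points[rest], values[rest], model, points[i][None, :])
                errs.append(pred[0] - values[i])
            rmse[fam] = float(np.sqrt(np.mean(np.square(errs))))
        except Exception as exc:
            rmse[fam] = math.nan
            flags[f"{fam}_failed"] = str(exc)
    valid = [f for f in families if not math.isnan(rmse.get(f, math.nan))]
    if not valid:
        raise VariogramError("every candidate family failed to fit")
    best = min(valid, key=lambda f: rmse[f])  # ties -> earliest in family order
    return SelectionResult(best, rmse, holdout, flags)


# ---------------------------------------------------------------------------
# era-binned isoscapes


@dataclass(frozen=True)
class GridSpec:
    x0: float
    y0: float
    cell: float
    nx: int
    ny: int

    def centers(self) -> np.ndarray:
        xs = self.x0 + self.cell * (np.arange(self.nx) + 0.5)
        ys = self.y0 + self.cell * (np.arange(self.ny) + 0.5)
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    @staticmethod
    def for_sites(sites_xy: np.ndarray, cell: float = 50.0) -> "GridSpec":
        x0 = float(sites_xy[:, 0].min()) - cell
        y0 = float(sites_xy[:, 1].min()) - cell
        nx = int(math.ceil((sites_xy[:, 0].max() + cell - x0) / cell))
        ny = int(math.ceil((sites_xy[:, 1].max() + cell - y0) / cell))
        return GridSpec(x0, y0, cell, max(nx, 1), max(ny, 1))


@dataclass
class Isoscape:
    variable: str
    era: EraBin
    grid: GridSpec
    predictions: np.ndarray  # (ny, nx), nan outside mask
    variances: np.ndarray  # (ny, nx)
    mask: np.ndarray  # (ny, nx) bool, inside mapped domain
    model: VariogramModel
    cv_rmse: float
    site_values: dict[str, float] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        """Mean prediction over the masked domain."""
        return float(np.nanmean(np.where(self.mask, self.predictions, np.nan)))


def site_era_means(
    samples: Iterable[CoreSample],
    dated: Mapping[tuple[str, float, float], tuple[float, EraBin | None]],
    variable: str,
) -> dict[str, dict[str, float]]:
    """Per-era, per-site unweighted mean of era-assigned sample values.

    ``dated`` maps (site_id, top, bottom) to (mean_year, era) as produced
    by the chronology stage.  Missing values are skipped, never imputed.
    """
    acc: dict[str, dict[str, list[float]]] = {}
    for s in samples:
        key = (s.site_id, s.interval.top, s.interval.bottom)
        if key not in dated:
            continue
        _, era = dated[key]
        if era is None:
            continue
        v = getattr(s, variable) if variable != "cn_molar" else s.cn_molar
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        acc.setdefault(era.label, {}).setdefault(s.site_id, []).append(float(v))
    return {
        era: {sid: float(np.mean(vals)) for sid, vals in sites.items()}
        for era, sites in acc.items()
    }


def build_isoscapes(
    samples: Iterable[CoreSample],
    dated: Mapping[tuple[str, float, float], tuple[float, EraBin | None]],
    sites: Sequence[CoreSite],
    eras: Sequence[EraBin],
    variable: str,
    grid_spec: GridSpec | None = None,
    force_family: str | None = None,
    families: Sequence[str] = FAMILIES,
    seed: int = 0,
    cell: float = 50.0,
) -> list[Isoscape]:
    """Kriged map per era for one variable.

    Per era: site value = mean of that site's samples dated into the era;
    the variogram family is selected by hold-out CV unless ``force_family``
    is given (the study forces spherical so era-to-era differences are a
    function of the data, not the interpolator); the map is masked to the
    convex hull of the contributing sites buffered by one grid cell.
    Eras with fewer than 4 sites are skipped with a warning flag.
    """
    samples = list(samples)
    site_map = {s.site_id: s for s in sites}
    by_era = site_era_means(samples, dated, variable)
    if grid_spec is None:
        xy = np.array([[s.x, s.y] for s in sites])
        grid_spec = GridSpec.for_sites(xy, cell=cell)
    targets = grid_spec.centers()

    out: list[Isoscape] = []
    for era in eras:
        vals_by_site = by_era.get(era.label, {})
        if len(vals_by_site) < 4:
            continue  # skipped: too few sites for a map
        sids = sorted(vals_by_site)
        pts = np.array([[site_map[s].x, site_map[s].y] for s in sids])
        vals = np.array([vals_by_site[s] for s in sids])

        cv_rmse = math.nan
        if force_family is not None:
            emp = empirical_variogram(pts, vals)
            model = fit_variogram(emp, force_family)
        else:
            sel = select_variogram(pts, vals, families=families, seed=seed)
            cv_rmse = sel.rmse[sel.best_family]
            emp = empirical_variogram(pts, vals)
            model = fit_variogram(emp, sel.best_family)

        hull = MultiPoint([tuple(p) for p in pts]).convex_hull.buffer(grid_spec.cell)
        mask_flat = np.array([hull.contains(Point(*t)) or hull.touches(Point(*t))
                              for t in targets])
        preds = np.full(len(targets), np.nan)
        variances = np.full(len(targets), np.nan)
        if mask_flat.any():
            p, v = krige(pts, vals, model, targets[mask_flat])
            preds[mask_flat] = p
            variances[mask_flat] = v
        shape = (grid_spec.ny, grid_spec.nx)
        out.append(
            Isoscape(
                variable=variable,
                era=era,
                grid=grid_spec,
                predictions=preds.reshape(shape),
                variances=variances.reshape(shape),
                mask=mask_flat.reshape(shape),
                model=model,
                cv_rmse=cv_rmse,
                site_values=dict(zip(sids, vals.tolist())),
            )
        )
    return out


# ---------------------------------------------------------------------------
# output


def write_ascii_grid(iso: Isoscape, path: str | Path, nodata: float = -9999.0) -> None:
    """ESRI ASCII grid of the predictions plus a JSON sidecar of metadata."""
    g = iso.grid
    arr = np.where(iso.mask & np.isfinite(iso.predictions), iso.predictions, nodata)
    lines = [
        f"ncols {g.nx}",
        f"nrows {g.ny}",
        f"xllcorner {g.x0:.6f}",
        f"yllcorner {g.y0:.6f}",
        f"cellsize {g.cell:.6f}",
        f"NODATA_value {nodata:.1f}",
    ]
    for row in arr[::-1]:  # ASCII grids run north to south
        lines.append(" ".join(f"{v:.6f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    sidecar = {
        "variable": iso.variable,
        "era": iso.era.label,
        "family": iso.model.family,
        "nugget": iso.model.nugget,
        "partial_sill": iso.model.partial_sill,
        "range_m": iso.model.range_m,
        "cv_rmse": None if math.isnan(iso.cv_rmse) else iso.cv_rmse,
        "n_sites": len(iso.site_values),
    }
    Path(str(path) + ".json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=1), encoding="utf-8"
    )
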