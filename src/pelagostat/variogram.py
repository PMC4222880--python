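"""Bidirectional variography of log-biomass and the stability envelope test.

The sampling runs along parallel transects, so spatial structure is resolved
in two directions: along transects (fine 1-nm resolution) and across them
(multiples of the transect spacing).  Empirical variograms are computed with
the classical Matheron estimator inside angular direction classes, modelled
as nugget + nested spherical components with direction-specific ranges
(geometric anisotropy, shared sills), and the interannual stability of the
spatial structure is tested against a simulation envelope around the
multi-year mean variogram.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

DIRECTIONS = ("along", "across")


class VariogramFitError(RuntimeError):
    """Raised when the weighted least-squares fit fails to converge.

    Carries ``best_model``, the best parameter set reached before failure.
    """

    def __init__(self, message: str, best_model: "VariogramModel | None" = None):
        super().__init__(message)
        self.best_model = best_model


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------


def _sph(r: np.ndarray) -> np.ndarray:
    """Unit spherical variogram: 1.5 r - 0.5 r^3 for r <= 1, else 1."""
    r = np.minimum(np.asarray(r, dtype=float), 1.0)
    return 1.5 * r - 0.5 * r**3


@dataclass(frozen=True)
class SphericalStructure:
    """One spherical component: sill (variance) and per-direction ranges (nm)."""

    sill: float
    range_along: float
    range_across: float

    def __post_init__(self) -> None:
        if self.sill < 0:
            raise ValueError("sill must be >= 0")
        if self.range_along <= 0 or self.range_across <= 0:
            raise ValueError("ranges must be > 0")


@dataclass(frozen=True)
class VariogramModel:
    """Nugget + nested spherical variogram with geometric anisotropy."""

    nugget: float
    structures: tuple[SphericalStructure, ...] = ()
    fit_info: Mapping | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        object.__setattr__(self, "structures", tuple(self.structures))

    @property
    def total_sill(self) -> float:
        return self.nugget + sum(s.sill for s in self.structures)

    def gamma_directional(self, h, direction: str) -> np.ndarray:
        """Semivariance at scalar lag distances taken purely in one direction."""
        h = np.abs(np.asarray(h, dtype=float))
        g = np.where(h > 0, self.nugget, 0.0)
        for s in self.structures:
            rng = s.range_along if direction == "along" else s.range_across
            g = g + s.sill * _sph(h / rng)
        return g

    def gamma_vector(self, h_along, h_across) -> np.ndarray:
        """Semivariance for separation vectors given by (along, across) parts."""
        ha = np.asarray(h_along, dtype=float)
        hx = np.asarray(h_across, dtype=float)
        h2 = ha**2 + hx**2
        g = np.where(h2 > 0, self.nugget, 0.0)
        for s in self.structures:
            r = np.sqrt((ha / s.range_along) ** 2 + (hx / s.range_across) ** 2)
            g = g + s.sill * _sph(r)
        return g

    def covariance(self, h_along, h_across) -> np.ndarray:
        """Stationary covariance C(h) = total sill - gamma(h)."""
        return self.total_sill - self.gamma_vector(h_along, h_across)


# --------------------------------------------------------------------------
# empirical variogram
# --------------------------------------------------------------------------


@dataclass
class EmpiricalVariogram:
    """Directional experimental variogram on a regular lag grid.

    ``gamma`` is NaN at lags holding no pair (flagged, not an error);
    ``mean_dist`` is the average pair separation inside each lag class, used
    when comparing against a model curve without binning bias.
    """

    direction: str
    lag_centres: np.ndarray
    gamma: np.ndarray
    n_pairs: np.ndarray
    mean_dist: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lag_centres) <= 0):
            raise ValueError("lag_centres must be strictly increasing")


@dataclass
class PairPlan:
    """Precomputed pair indices and lag classes for one direction.

    Separating pair bookkeeping from value differencing lets the simulation
    envelope re-evaluate the variogram of thousands of fields on the same
    geometry at matrix speed.
    """

    direction: str
    lag_centres: np.ndarray
    i: np.ndarray
    j: np.ndarray
    bins: np.ndarray
    n_pairs: np.ndarray
    mean_dist: np.ndarray


def build_pair_plan(
    points: np.ndarray,
    direction: str = "along",
    lag_width: float = 2.0,
    n_lags: int = 25,
    angular_tol: float = 15.0,
    azimuth: float = 0.0,
) -> PairPlan:
    """Enumerate the i<j pairs of a direction class and their lag bins."""
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if lag_width <= 0:
        raise ValueError("lag_width must be > 0")
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points")
    ii, jj = np.triu_indices(n, k=1)
    dx = pts[jj, 0] - pts[ii, 0]
    dy = pts[jj, 1] - pts[ii, 1]
    a = math.radians(azimuth)
    ha = dx * math.sin(a) + dy * math.cos(a)
    hx = dx * math.cos(a) - dy * math.sin(a)
    r = np.hypot(ha, hx)
    if direction == "along":
        ang = np.degrees(np.arctan2(np.abs(hx), np.abs(ha)))
    else:
        ang = np.degrees(np.arctan2(np.abs(ha), np.abs(hx)))
    keep = (r > 0) & (ang <= angular_tol)
    bins = np.floor(r[keep] / lag_width).astype(int)
    inside = bins < n_lags
    ii, jj, bins, r = ii[keep][inside], jj[keep][inside], bins[inside], r[keep][inside]
    n_pairs = np.bincount(bins, minlength=n_lags)
    with np.errstate(invalid="ignore"):
        mean_dist = np.bincount(bins, weights=r, minlength=n_lags) / n_pairs
    centres = (np.arange(n_lags) + 0.5) * lag_width
    return PairPlan(direction, centres, ii, jj, bins, n_pairs, mean_dist)


def gamma_from_plan(values: np.ndarray, plan: PairPlan) -> np.ndarray:
    """Matheron estimator on a pair plan; rows of a 2-D input are fields."""
    v = np.asarray(values, dtype=float)
    one = v.ndim == 1
    v = np.atleast_2d(v)
    d2 = (v[:, plan.i] - v[:, plan.j]) ** 2
    n_lags = len(plan.lag_centres)
    sums = np.empty((v.shape[0], n_lags))
    for k in range(v.shape[0]):
        sums[k] = np.bincount(plan.bins, weights=d2[k], minlength=n_lags)
    with np.errstate(invalid="ignore"):
        g = 0.5 * sums / plan.n_pairs
    return g[0] if one else g


def empirical_variogram(
    points: np.ndarray,
    values: np.ndarray,
    direction: str = "along",
    lag_width: float = 2.0,
    n_lags: int = 25,
    angular_tol: float = 15.0,
    azimuth: float = 0.0,
) -> EmpiricalVariogram:
    """Directional Matheron variogram gamma(h) = sum (zi-zj)^2 / (2 N(h)).

    Pairs are counted once (i < j) and assigned to the ``along`` class when
    the separation vector lies within ``angular_tol`` degrees of the transect
    azimuth, to ``across`` within the same tolerance of its perpendicular.
    Empty lags are flagged with NaN.
    """
    plan = build_pair_plan(points, direction, lag_width, n_lags, angular_tol, azimuth)
    g = gamma_from_plan(np.asarray(values, dtype=float), plan)
    return EmpiricalVariogram(direction, plan.lag_centres, g, plan.n_pairs, plan.mean_dist)


# --------------------------------------------------------------------------
# standardization and the mean variogram
# --------------------------------------------------------------------------


def standardize_by_year(years: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Z-score values within each survey year (mean 0, sample variance 1).

    Removes the annual biomass level so the multi-year mean variogram and
    the envelope test compare spatial *structure*, not abundance.
    """
    years = np.asarray(years)
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    for y in np.unique(years):
        m = years == y
        if m.sum() < 2:
            raise ValueError(f"year {y} has fewer than 2 records")
        sd = v[m].std(ddof=1)
        if sd == 0:
            raise ValueError(f"year {y} has zero within-year variance")
        out[m] = (v[m] - v[m].mean()) / sd
    return out


@dataclass
class MeanVariogramResult:
    """Pooled multi-year variogram per direction plus the fitted model."""

    along: EmpiricalVariogram
    across: EmpiricalVariogram
    model: "VariogramModel | None"


def mean_variogram(
    points_by_year: Sequence[np.ndarray],
    values_by_year: Sequence[np.ndarray],
    lag_width: float = 2.0,
    n_lags: int = 25,
    angular_tol: float = 15.0,
    azimuth: float = 0.0,
    n_structures: int = 2,
    fit: bool = True,
) -> MeanVariogramResult:
    """Mean variogram over years: pairs pooled strictly within years.

    Equivalent to the pair-count-weighted average of the annual variograms
    lag by lag; no pair ever mixes two survey years.
    """
    if len(points_by_year) < 2:
        raise ValueError("need at least 2 years")
    result: dict[str, EmpiricalVariogram] = {}
    for direction in DIRECTIONS:
        sums = np.zeros(n_lags)
        counts = np.zeros(n_lags, dtype=int)
        dist_sums = np.zeros(n_lags)
        for pts, vals in zip(points_by_year, values_by_year):
            plan = build_pair_plan(pts, direction, lag_width, n_lags, angular_tol, azimuth)
            d2 = (np.asarray(vals, float)[plan.i] - np.asarray(vals, float)[plan.j]) ** 2
            sums += np.bincount(plan.bins, weights=d2, minlength=n_lags)
            counts += plan.n_pairs
            finite = plan.n_pairs > 0
            dist_sums[finite] += plan.mean_dist[finite] * plan.n_pairs[finite]
        with np.errstate(invalid="ignore"):
            gamma = 0.5 * sums / counts
            mean_dist = dist_sums / counts
        centres = (np.arange(n_lags) + 0.5) * lag_width
        result[direction] = EmpiricalVariogram(direction, centres, gamma, counts, mean_dist)
    model = None
    if fit:
        model = fit_variogram_model(result["along"], result["across"], n_structures)
    return MeanVariogramResult(result["along"], result["across"], model)


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------


def _model_from_params(p: np.ndarray, n_structures: int) -> VariogramModel:
    structures = []
    for k in range(n_structures):
        sill, ra, rx = p[1 + 3 * k : 4 + 3 * k]
        structures.append(SphericalStructure(sill, ra, rx))
    return VariogramModel(nugget=p[0], structures=tuple(structures))


def fit_variogram_model(
    emp_along: EmpiricalVariogram,
    emp_across: EmpiricalVariogram,
    n_structures: int = 1,
) -> VariogramModel:
    """Joint weighted least-squares fit of both directional variograms.

    The model is nugget + ``n_structures`` spherical components with shared
    sills and direction-specific ranges; residuals are weighted by the square
    root of the pair counts.  Several deterministic starts are tried and the
    lowest objective wins; the winning objective and residual diagnostics are
    attached as ``fit_info``.
    """
    if n_structures not in (1, 2):
        raise ValueError("n_structures must be 1 or 2")
    lags, gammas, weights, dirs = [], [], [], []
    for emp in (emp_along, emp_across):
        ok = np.isfinite(emp.gamma) & (emp.n_pairs > 0)
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 non-empty lags in direction {emp.direction}")
        h = np.where(np.isfinite(emp.mean_dist[ok]), emp.mean_dist[ok], emp.lag_centres[ok])
        lags.append(h)
        gammas.append(emp.gamma[ok])
        weights.append(np.sqrt(emp.n_pairs[ok].astype(float)))
        dirs.append(emp.direction)

    max_lag = max(h.max() for h in lags)
    sill_guess = max(float(np.average(g, weights=w)) for g, w in zip(gammas, weights))
    sill_guess = max(sill_guess, 1e-8)

    def residuals(p):
        model = _model_from_params(p, n_structures)
        res = []
        for h, g, w, d in zip(lags, gammas, weights, dirs):
            res.append(w * (model.gamma_directional(h, d) - g))
        return np.concatenate(res)

    lo = [0.0] + [0.0, 1e-3, 1e-3] * n_structures
    hi = [10 * sill_guess] + [10 * sill_guess, 8 * max_lag, 8 * max_lag] * n_structures
    starts = []
    if n_structures == 1:
        for frac in (0.33, 0.8):
            for nug in (1e-6, 0.3 * sill_guess):
                starts.append([nug, sill_guess, frac * max_lag, frac * max_lag])
    else:
        for f1, f2 in ((0.1, 0.6), (0.25, 1.2), (0.05, 0.3)):
            for nug in (1e-6, 0.2 * sill_guess):
                starts.append(
                    [nug, 0.5 * sill_guess, f1 * max_lag, f1 * max_lag,
                     0.5 * sill_guess, f2 * max_lag, f2 * max_lag]
                )

    best = None
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        try:
            res = least_squares(residuals, p0, bounds=(lo, hi), method="trf", x_scale="jac")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise VariogramFitError("all optimisation starts failed", best_model=None)
    model = _model_from_params(best.x, n_structures)
    info = {"objective": float(best.cost), "status": int(best.status),
            "converged": bool(best.status > 0)}
    model = VariogramModel(model.nugget, model.structures, fit_info=info)
    if not info["converged"]:
        raise VariogramFitError(
            f"variogram fit did not converge (status {best.status})", best_model=model
        )
    return model


# --------------------------------------------------------------------------
# simulation envelope and stability test
# --------------------------------------------------------------------------


@dataclass
class VariogramEnvelope:
    """Pointwise 95% band of simulated variograms around a mean model."""

    lag_centres: Mapping[str, np.ndarray]
    lower: Mapping[str, np.ndarray]
    upper: Mapping[str, np.ndarray]
    n_sim: int

    def __post_init__(self) -> None:
        for d in self.lower:
            bad = np.isfinite(self.lower[d]) & np.isfinite(self.upper[d])
            if np.any(self.lower[d][bad] > self.upper[d][bad]):
                raise ValueError("envelope lower bound exceeds upper bound")


def variogram_envelope(
    model: VariogramModel,
    locations: np.ndarray,
    n_sim: int = 1000,
    seed: int = 0,
    lag_width: float = 2.0,
    n_lags: int = 25,
    angular_tol: float = 15.0,
    azimuth: float = 0.0,
    n_bands: int = 180,
    standardize: bool = True,
    quantiles: tuple[float, float] = (0.025, 0.975),
) -> VariogramEnvelope:
    """Simulate ``n_sim`` Gaussian fields from ``model`` at the survey
    locations and return per-lag 2.5%/97.5% bounds of their variograms.

    Fields are z-scored before variography when ``standardize`` is true,
    mirroring the treatment of the annual survey data the envelope is
    compared with.
    """
    from .simulate import simulate_gaussian_fields  # local import, avoids cycle

    fields = simulate_gaussian_fields(
        locations, model, seed=seed, n_bands=n_bands, n_fields=n_sim, azimuth=azimuth
    )
    if standardize:
        mu = fields.mean(axis=1, keepdims=True)
        sd = fields.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        fields = (fields - mu) / sd
    centres, lower, upper = {}, {}, {}
    for direction in DIRECTIONS:
        plan = build_pair_plan(locations, direction, lag_width, n_lags, angular_tol, azimuth)
        g = gamma_from_plan(fields, plan)
        centres[direction] = plan.lag_centres
        if n_sim >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN (empty) lags
                lo = np.nanquantile(g, quantiles[0], axis=0)
                up = np.nanquantile(g, quantiles[1], axis=0)
        else:
            lo = up = g[0]
        empty = plan.n_pairs == 0
        lo[empty] = np.nan
        up[empty] = np.nan
        lower[direction], upper[direction] = lo, up
    return VariogramEnvelope(centres, lower, upper, n_sim)


@dataclass
class StabilityResult:
    year: int
    stable: bool
    frac_outside: float
    n_lags_checked: int


def test_annual_stability(
    annual_variograms: Mapping[int, Mapping[str, EmpiricalVariogram]],
    envelope: VariogramEnvelope,
    tolerance_fraction: float = 0.05,
) -> dict[int, StabilityResult]:
    """Flag years whose variogram leaves the envelope at too many lags.

    A year is unstable when the fraction of its non-empty lags falling
    outside the pointwise band exceeds ``tolerance_fraction``.
    """
    results: dict[int, StabilityResult] = {}
    for year, per_dir in annual_variograms.items():
        outside = 0
        checked = 0
        for direction, emp in per_dir.items():
            if direction not in envelope.lower:
                raise ValueError(f"envelope lacks direction {direction!r}")
            if len(emp.lag_centres) != len(envelope.lag_centres[direction]) or not np.allclose(
                emp.lag_centres, envelope.lag_centres[direction]
            ):
                raise ValueError("annual variogram and envelope lag grids differ")
            lo = envelope.lower[direction]
            up = envelope.upper[direction]
            ok = np.isfinite(emp.gamma) & np.isfinite(lo) & np.isfinite(up)
            checked += int(ok.sum())
            outside += int(((emp.gamma[ok] < lo[ok]) | (emp.gamma[ok] > up[ok])).sum())
        frac = outside / checked if checked else 0.0
        results[year] = StabilityResult(
            year=int(year), stable=frac <= tolerance_fraction,
            frac_outside=frac, n_lags_checked=checked,
        )
    return results
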