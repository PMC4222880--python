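"""Spatial-distribution indicators.

Centre of gravity and inertia (with principal axes and the 1-sigma inertia
ellipse), anisotropic recursive patch identification, empirical orthogonal
functions (EOF) of the annual spatial fields, and the pointwise temporal CV
of relative biomass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned-in-principal-frame ellipse: centre, semi-axes, orientation.

    ``angle_deg`` is the direction of the semi-major axis, degrees
    counter-clockwise from the +x axis.
    """

    cx: float
    cy: float
    semi_major: float
    semi_minor: float
    angle_deg: float

    @property
    def area(self) -> float:
        return math.pi * self.semi_major * self.semi_minor


@dataclass
class GravityStats:
    """Centre of gravity, inertia and principal axes of a weighted point set.

    Inertia is the biomass-weighted mean squared distance to the centre of
    gravity (nm^2); the two principal-axis variances sum to it, and the
    1-sigma inertia ellipse has semi-axes equal to their square roots.
    """

    cg: np.ndarray
    inertia: float
    axis_directions: np.ndarray  # (2, 2), rows are unit vectors
    axis_variances: np.ndarray  # (2,), decreasing
    ellipse: Ellipse


def centre_of_gravity(points, weights) -> np.ndarray:
    """Biomass-weighted mean location."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be > 0")
    return (w[:, None] * pts).sum(axis=0) / total


def inertia(points, weights) -> GravityStats:
    """Weighted dispersion summary around the centre of gravity."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    w = np.asarray(weights, dtype=float)
    cg = centre_of_gravity(pts, w)
    d = pts - cg
    cov = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / w.sum()
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T
    ell = Ellipse(
        cx=float(cg[0]), cy=float(cg[1]),
        semi_major=float(np.sqrt(evals[0])), semi_minor=float(np.sqrt(evals[1])),
        angle_deg=float(math.degrees(math.atan2(evecs[0, 1], evecs[0, 0]))),
    )
    return GravityStats(
        cg=cg, inertia=float(np.trace(cov)),
        axis_directions=evecs, axis_variances=evals, ellipse=ell,
    )


# --------------------------------------------------------------------------
# patches
# --------------------------------------------------------------------------


@dataclass
class Patch:
    """A spatial patch of high biomass assembled by the greedy recursion."""

    member_indices: np.ndarray
    cg: np.ndarray
    inertia: float
    biomass: float
    biomass_share: float
    retained: bool
    stats: GravityStats


def identify_patches(
    points,
    values,
    d_along: float = 6.0,
    d_across: float = 24.0,
    min_share: float = 0.10,
    azimuth: float = 0.0,
) -> list[Patch]:
    """Anisotropic recursive patch identification.

    Presence samples are processed in decreasing biomass order.  The richest
    sample seeds the first patch; each subsequent sample joins the patch whose
    *current* (biomass-weighted, running) centre of gravity is nearest in the
    anisotropy-scaled distance d = sqrt((dAlong/d_along)^2 + (dAcross/d_across)^2)
    provided d <= 1, otherwise it founds a new patch.  Distance ties go to the
    earlier-created patch; equal-biomass samples are processed in input order.
    Patches holding less than ``min_share`` of the total biomass are flagged
    non-retained but kept, so biomass accounting stays closed.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    v = np.asarray(values, dtype=float)
    if d_along <= 0 or d_across <= 0:
        raise ValueError("patch distance thresholds must be > 0")
    present = np.flatnonzero(v > 0)
    if present.size == 0:
        raise ValueError("no presence points")
    total = float(v[present].sum())

    a = math.radians(azimuth)
    along = pts[:, 0] * math.sin(a) + pts[:, 1] * math.cos(a)
    across = pts[:, 0] * math.cos(a) - pts[:, 1] * math.sin(a)

    order = present[np.argsort(-v[present], kind="stable")]
    members: list[list[int]] = []
    cg_along: list[float] = []
    cg_across: list[float] = []
    weight: list[float] = []
    for idx in order:
        if members:
            da = (along[idx] - np.asarray(cg_along)) / d_along
            dx = (across[idx] - np.asarray(cg_across)) / d_across
            dist = np.sqrt(da**2 + dx**2)
            k = int(np.argmin(dist))  # argmin returns the earliest patch on ties
            if dist[k] <= 1.0:
                wnew = weight[k] + v[idx]
                cg_along[k] = (cg_along[k] * weight[k] + along[idx] * v[idx]) / wnew
                cg_across[k] = (cg_across[k] * weight[k] + across[idx] * v[idx]) / wnew
                weight[k] = wnew
                members[k].append(int(idx))
                continue
        members.append([int(idx)])
        cg_along.append(float(along[idx]))
        cg_across.append(float(across[idx]))
        weight.append(float(v[idx]))

    patches = []
    for mem in members:
        mem_arr = np.asarray(mem, dtype=int)
        stats = inertia(pts[mem_arr], v[mem_arr])
        biomass = float(v[mem_arr].sum())
        share = biomass / total
        patches.append(
            Patch(
                member_indices=mem_arr, cg=stats.cg, inertia=stats.inertia,
                biomass=biomass, biomass_share=share,
                retained=share >= min_share, stats=stats,
            )
        )
    return patches


# --------------------------------------------------------------------------
# EOF
# --------------------------------------------------------------------------


@dataclass
class EofResult:
    """Empirical orthogonal function decomposition of a year x location field."""

    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    year_scores: np.ndarray  # (n_years, n_axes)
    point_loadings: np.ndarray  # (n_axes, n_locations)
    row_means: np.ndarray
    standardization: str

    def reconstruct(self) -> np.ndarray:
        """Rebuild the standardized matrix from all axes."""
        return self.year_scores @ self.point_loadings + self.row_means[:, None]


def eof(annual_maps, standardization: str = "relative") -> EofResult:
    """EOF of a complete year x location matrix.

    Rows (years) are first standardized — ``relative`` divides each year by
    its total so the comparison is independent of annual biomass levels,
    ``zscore`` z-scores each year, ``none`` leaves rows untouched — then each
    year is centred on its spatial mean and decomposed by SVD.  Axis k
    explains ``pct_variance[k]`` of the interannual variance of spatial
    distributions; ``year_scores`` are the year coordinates on the axes and
    ``point_loadings`` the spatial patterns.
    """
    M = np.asarray(annual_maps, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need a year x location matrix with >= 2 of each")
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix has missing cells; restrict to common locations")
    if standardization == "relative":
        totals = M.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise ValueError("relative standardization needs positive yearly totals")
        M = M / totals
    elif standardization == "zscore":
        sd = M.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("zscore standardization needs within-year variance")
        M = (M - M.mean(axis=1, keepdims=True)) / sd
    elif standardization != "none":
        raise ValueError("standardization must be 'relative', 'zscore' or 'none'")
    row_means = M.mean(axis=1)
    C = M - row_means[:, None]
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    lam = s**2 / max(M.shape[1] - 1, 1)
    total = lam.sum()
    pct = 100.0 * lam / total if total > 0 else np.full_like(lam, np.nan)
    return EofResult(
        eigenvalues=lam, pct_variance=pct, year_scores=U * s,
        point_loadings=Vt, row_means=row_means, standardization=standardization,
    )


def year_axis_correlations(result: EofResult, n_axes: int = 2) -> np.ndarray:
    """Correlation of each (centred) annual map with the first axes' spatial
    patterns; sign changes across years indicate unstable distributions."""
    C = result.reconstruct() - result.row_means[:, None]
    k = min(n_axes, result.point_loadings.shape[0])
    out = np.empty((C.shape[0], k))
    for ax in range(k):
        load = result.point_loadings[ax]
        denom = np.linalg.norm(load) * np.linalg.norm(C, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, ax] = (C @ load) / denom
    return out


# --------------------------------------------------------------------------
# pointwise CV
# --------------------------------------------------------------------------


def pointwise_cv(relative_biomass, atol: float = 1e-6) -> np.ndarray:
    """Temporal coefficient of variation per location of relative biomass.

    Input rows are annual relative-biomass vectors (each summing to 1, checked
    to ``atol``); returns sample SD across years / mean across years per
    location, NaN where the species never occurred.  Values above 1 indicate
    overdispersion, i.e. a change of geographical location between years.
    """
    R = np.asarray(relative_biomass, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise ValueError("need >= 2 years of relative biomass")
    sums = R.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > atol):
        raise ValueError("each year's relative biomass must sum to 1")
    mean = R.mean(axis=0)
    sd = R.std(axis=0, ddof=1)
    out = np.full(R.shape[1], np.nan)
    nz = mean > 0
    out[nz] = sd[nz] / mean[nz]
    return out
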