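"""Ordinary kriging of log-biomass with an anisotropic moving neighbourhood,
average/variability maps and recurrent/occasional/unfavourable classification.

Because sampling runs along parallel transects, the neighbour search ellipse
is stretched across transects (so every grid node sees data from at least two
transects) and kept tight along them.  Maps are produced and analysed on the
log scale; no lognormal back-transform is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Polygon

from .variogram import VariogramModel


@dataclass(frozen=True)
class NeighbourhoodSpec:
    """Anisotropic moving-neighbourhood search parameters (nm / counts)."""

    radius_along: float = 12.0
    radius_across: float = 30.0
    min_neighbours: int = 4
    max_neighbours: int = 32

    def __post_init__(self) -> None:
        if self.radius_along <= 0 or self.radius_across <= 0:
            raise ValueError("search radii must be > 0")
        if not (1 <= self.min_neighbours <= self.max_neighbours):
            raise ValueError("need 1 <= min_neighbours <= max_neighbours")


@dataclass
class Grid:
    """Regular lattice of node centres with a domain mask."""

    x: np.ndarray  # (nx,)
    y: np.ndarray  # (ny,)
    mask: np.ndarray  # (ny, nx) bool

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.y), len(self.x))

    def nodes(self) -> np.ndarray:
        """All node coordinates, shape (ny*nx, 2), row-major over (y, x)."""
        xx, yy = np.meshgrid(self.x, self.y)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.x, other.x)
            and np.allclose(self.y, other.y)
            and np.array_equal(self.mask, other.mask)
        )


def make_grid(points, resolution: float = 1.0, domain: Polygon | None = None) -> Grid:
    """Build the kriging grid: node centres every ``resolution`` nm over the
    bounding box, masked to the convex hull of the sample locations
    intersected with the survey domain polygon (when given)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    region = hull if domain is None else hull.intersection(domain)
    x0, y0, x1, y1 = pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max()
    xs = np.arange(x0 + resolution / 2, x1 + resolution / 2, resolution)
    ys = np.arange(y0 + resolution / 2, y1 + resolution / 2, resolution)
    if len(xs) == 0:
        xs = np.array([(x0 + x1) / 2])
    if len(ys) == 0:
        ys = np.array([(y0 + y1) / 2])
    xx, yy = np.meshgrid(xs, ys)
    mask = shapely.contains_xy(region.buffer(1e-9), xx.ravel(), yy.ravel()).reshape(xx.shape)
    return Grid(x=xs, y=ys, mask=mask)


@dataclass
class KrigedMap:
    """Ordinary-kriging predictions and variances on a masked grid."""

    grid: Grid
    predictions: np.ndarray  # (ny, nx), NaN outside mask / skipped nodes
    kriging_variance: np.ndarray
    n_neighbours_used: np.ndarray  # int, 0 where skipped
    n_singular: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.grid.x, self.grid.y)
        ok = np.isfinite(self.predictions)
        return pd.DataFrame(
            {
                "x": xx[ok], "y": yy[ok],
                "prediction": self.predictions[ok],
                "kriging_variance": self.kriging_variance[ok],
                "n_neighbours": self.n_neighbours_used[ok],
            }
        )


def krige(
    points,
    values,
    model: VariogramModel,
    grid: Grid,
    nbhd: NeighbourhoodSpec = NeighbourhoodSpec(),
    azimuth: float = 0.0,
) -> KrigedMap:
    """Ordinary kriging on the grid with an anisotropic moving neighbourhood.

    For each masked-in node the ``nbhd.max_neighbours`` data points nearest in
    the anisotropy-scaled distance (and within the unit search ellipse) feed
    an ordinary-kriging system; weights sum to one.  Nodes with fewer than
    ``min_neighbours`` candidates stay masked; a singular system flags the
    node (NaN) without aborting the map.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    v = np.asarray(values, dtype=float)
    n = len(pts)
    if n < nbhd.min_neighbours:
        raise ValueError("fewer data points than min_neighbours")

    a = math.radians(azimuth)
    rot = np.array([[math.sin(a), math.cos(a)], [math.cos(a), -math.sin(a)]])
    ax_data = pts @ rot.T  # columns: along, across
    scaled_data = ax_data / np.array([nbhd.radius_along, nbhd.radius_across])
    tree = cKDTree(scaled_data)

    # full data-data covariance once; node systems are subsets of it
    d_al = ax_data[:, 0][:, None] - ax_data[:, 0][None, :]
    d_ax = ax_data[:, 1][:, None] - ax_data[:, 1][None, :]
    C = model.covariance(d_al, d_ax)

    ny, nx = grid.shape
    pred = np.full((ny, nx), np.nan)
    krig_var = np.full((ny, nx), np.nan)
    n_used = np.zeros((ny, nx), dtype=int)
    n_singular = 0

    nodes = grid.nodes()
    ax_nodes = nodes @ rot.T
    scaled_nodes = ax_nodes / np.array([nbhd.radius_along, nbhd.radius_across])
    k = min(nbhd.max_neighbours, n)
    dist, idx = tree.query(scaled_nodes, k=k, distance_upper_bound=1.0 + 1e-12)
    dist = np.atleast_2d(dist.reshape(len(nodes), -1))
    idx = np.atleast_2d(idx.reshape(len(nodes), -1))

    flat_mask = grid.mask.ravel()
    sill = model.total_sill
    for node_i in range(len(nodes)):
        if not flat_mask[node_i]:
            continue
        sel = idx[node_i][np.isfinite(dist[node_i])]
        m = len(sel)
        if m < nbhd.min_neighbours:
            continue
        iy, ix = divmod(node_i, nx)
        Cm = C[np.ix_(sel, sel)]
        c0 = model.covariance(
            ax_nodes[node_i, 0] - ax_data[sel, 0],
            ax_nodes[node_i, 1] - ax_data[sel, 1],
        )
        A = np.empty((m + 1, m + 1))
        A[:m, :m] = Cm
        A[m, :m] = 1.0
        A[:m, m] = 1.0
        A[m, m] = 0.0
        b = np.append(c0, 1.0)
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            n_singular += 1
            continue
        w, mu = sol[:m], sol[m]
        pred[iy, ix] = float(w @ v[sel])
        krig_var[iy, ix] = max(float(sill - w @ c0 - mu), 0.0)
        n_used[iy, ix] = m
    if n_singular:
        warnings.warn(f"{n_singular} nodes skipped (singular kriging system)", stacklevel=2)
    return KrigedMap(grid, pred, krig_var, n_used, n_singular)


def average_variability_maps(annual_maps: list[KrigedMap]) -> tuple[np.ndarray, np.ndarray]:
    """Node-by-node mean and sample SD of the annual kriged maps."""
    if len(annual_maps) < 2:
        raise ValueError("need at least 2 annual maps")
    g0 = annual_maps[0].grid
    for m in annual_maps[1:]:
        if not m.grid.same_geometry(g0):
            raise ValueError("annual maps are on different grids")
    stack = np.stack([m.predictions for m in annual_maps])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_map = np.nanmean(stack, axis=0)
        sd_map = np.nanstd(stack, axis=0, ddof=1)
    return mean_map, sd_map


CATEGORY_LABELS = {0: "unfavourable", 1: "occasional", 2: "recurrent"}


@dataclass
class AreaClassification:
    """Recurrent / occasional / unfavourable area labels per grid node."""

    grid: Grid
    category: np.ndarray  # int codes, -1 outside mask
    mean_map: np.ndarray
    sd_map: np.ndarray
    median_mean: float
    median_sd: float

    def counts(self) -> dict[str, int]:
        return {lab: int((self.category == code).sum()) for code, lab in CATEGORY_LABELS.items()}

    def to_dataframe(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.grid.x, self.grid.y)
        ok = self.category >= 0
        return pd.DataFrame(
            {
                "x": xx[ok], "y": yy[ok],
                "mean": self.mean_map[ok], "sd": self.sd_map[ok],
                "category": [CATEGORY_LABELS[c] for c in self.category[ok]],
            }
        )


def classify_areas(mean_map, sd_map, grid: Grid) -> AreaClassification:
    """Median-split classification of the masked grid.

    With Mm/Ms the medians of the mean and SD maps over valid nodes:
    sd >= Ms -> occasional; sd < Ms and mean >= Mm -> recurrent; otherwise
    unfavourable ("at or above the median" counts as high).
    """
    mean_map = np.asarray(mean_map, dtype=float)
    sd_map = np.asarray(sd_map, dtype=float)
    valid = grid.mask & np.isfinite(mean_map) & np.isfinite(sd_map)
    if not valid.any():
        raise ValueError("empty mask: nothing to classify")
    mm = float(np.median(mean_map[valid]))
    ms = float(np.median(sd_map[valid]))
    cat = np.full(grid.shape, -1, dtype=int)
    occ = valid & (sd_map >= ms)
    rec = valid & ~occ & (mean_map >= mm)
    unf = valid & ~occ & ~rec
    cat[occ] = 1
    cat[rec] = 2
    cat[unf] = 0
    return AreaClassification(grid, cat, mean_map, sd_map, mm, ms)


def write_ascii_grid(path, grid: Grid, array, nodata: float = -9999.0) -> None:
    """Write a grid layer as an ESRI-ASCII raster (text interoperability)."""
    arr = np.asarray(array, dtype=float)
    res = float(grid.x[1] - grid.x[0]) if len(grid.x) > 1 else 1.0
    out = np.where(np.isfinite(arr), arr, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {len(grid.x)}\n")
        fh.write(f"nrows {len(grid.y)}\n")
        fh.write(f"xllcorner {grid.x[0] - res / 2}\n")
        fh.write(f"yllcorner {grid.y[0] - res / 2}\n")
        fh.write(f"cellsize {res}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in out[::-1]:  # ESRI rasters start at the top row
            fh.write(" ".join(f"{x:.6g}" for x in row) + "\n")
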