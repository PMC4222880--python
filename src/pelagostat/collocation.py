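"""Pairwise interspecific collocation at three spatial scales.

Global: intersection-over-union of the two populations' inertia ellipses.
Intermediate: IoU of the unions of their retained patch ellipses.
Local: co-occurrence (presence/absence), the local index of collocation (LIC,
the cosine between the two density vectors) and the signed dominance index,
plus seeded randomization tests against a spatially-unstructured null.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .distribution import Ellipse, Patch, identify_patches, inertia

_EPS_AREA = 1e-12


def ellipse_polygon(ellipse: Ellipse, n_vertices: int = 720) -> Polygon:
    """Polygonal approximation of an ellipse (relative area error < 1e-4)."""
    theta = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    a, b = ellipse.semi_major, ellipse.semi_minor
    rot = math.radians(ellipse.angle_deg)
    x = a * np.cos(theta)
    y = b * np.sin(theta)
    xr = ellipse.cx + x * math.cos(rot) - y * math.sin(rot)
    yr = ellipse.cy + x * math.sin(rot) + y * math.cos(rot)
    return Polygon(zip(xr, yr))


def ellipse_overlap(e1: Ellipse, e2: Ellipse, n_vertices: int = 720) -> float:
    """Intersection-over-union of two ellipse areas.

    0 when the ellipses are totally separated, 1 when identical.  A zero-area
    (degenerate) ellipse gives 0, unless both are the same degenerate point,
    which counts as identical (1).
    """
    deg1, deg2 = e1.area <= _EPS_AREA, e2.area <= _EPS_AREA
    if deg1 or deg2:
        if deg1 and deg2 and math.isclose(e1.cx, e2.cx) and math.isclose(e1.cy, e2.cy):
            return 1.0
        warnings.warn("degenerate (zero-area) ellipse in overlap; returning 0", stacklevel=2)
        return 0.0
    p1, p2 = ellipse_polygon(e1, n_vertices), ellipse_polygon(e2, n_vertices)
    union = p1.union(p2).area
    return p1.intersection(p2).area / union if union > 0 else 0.0


def patch_overlap(
    patches_i: list[Patch], patches_j: list[Patch], n_vertices: int = 720
) -> float:
    """IoU of the unions of the two species' retained patch inertia ellipses.

    Returns NaN (flagged by a warning) when either species has no retained
    patch with positive ellipse area.
    """
    def union_of(patches: list[Patch]):
        polys = [
            ellipse_polygon(p.stats.ellipse, n_vertices)
            for p in patches
            if p.retained and p.stats.ellipse.area > _EPS_AREA
        ]
        return unary_union(polys) if polys else None

    ui, uj = union_of(patches_i), union_of(patches_j)
    if ui is None or uj is None:
        warnings.warn("no retained patch with positive area; patch overlap undefined",
                      stacklevel=2)
        return float("nan")
    union = ui.union(uj).area
    return ui.intersection(uj).area / union if union > 0 else 0.0


def cooccurrence_index(zi, zj) -> float:
    """Fraction of points holding both species, among points holding at least
    one of them."""
    zi = np.asarray(zi, dtype=float)
    zj = np.asarray(zj, dtype=float)
    either = (zi > 0) | (zj > 0)
    if not either.any():
        raise ValueError("both species absent everywhere")
    both = (zi > 0) & (zj > 0)
    return float(both.sum()) / float(either.sum())


def local_index_of_collocation(zi, zj) -> float:
    """LIC = sum zi zj / sqrt(sum zi^2 sum zj^2), the cosine of the two
    density vectors: 1 for proportional densities, 0 for disjoint supports."""
    zi = np.asarray(zi, dtype=float)
    zj = np.asarray(zj, dtype=float)
    si, sj = float(zi @ zi), float(zj @ zj)
    if si <= 0 or sj <= 0:
        raise ValueError("a species is absent everywhere")
    return float(zi @ zj) / math.sqrt(si * sj)


def dominance_index(zi, zj) -> np.ndarray:
    """Signed relative biomass difference (zi - zj)/(zi + zj) per point.

    1 where only species i is present, -1 where only species j is, 0 where
    both are equally abundant; NaN (undefined) where both are absent.
    Antisymmetric under the species swap.
    """
    zi = np.asarray(zi, dtype=float)
    zj = np.asarray(zj, dtype=float)
    tot = zi + zj
    out = np.full(zi.shape, np.nan)
    nz = tot > 0
    out[nz] = (zi[nz] - zj[nz]) / tot[nz]
    return out


# --------------------------------------------------------------------------
# randomization test
# --------------------------------------------------------------------------


@dataclass
class RandomizationResult:
    index: str
    observed: float
    p_value: float
    null_mean: float
    n_resamples: int
    degenerate: bool = False


def randomization_test(
    index: str,
    zi,
    zj,
    n_resamples: int = 1000,
    seed: int = 0,
    method: str = "bootstrap",
) -> RandomizationResult:
    """Randomization test of a local collocation index.

    The null keeps the first species' spatial pattern and destroys the
    second's by resampling ``zj`` across sampling locations — with replacement
    (``bootstrap``, the default) or without (``permutation``).  The two-sided
    p-value uses the add-one estimator
    p = (1 + #{|null - mean(null)| >= |obs - mean(null)|}) / (n_resamples + 1),
    so the smallest attainable p is 1/(n_resamples + 1).  Deterministic given
    the seed.
    """
    if n_resamples < 99:
        raise ValueError("n_resamples must be >= 99")
    zi = np.asarray(zi, dtype=float)
    zj = np.asarray(zj, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(zj)
    if method == "bootstrap":
        samples = zj[rng.integers(0, n, size=(n_resamples, n))]
    elif method == "permutation":
        samples = np.stack([rng.permutation(zj) for _ in range(n_resamples)])
    else:
        raise ValueError("method must be 'bootstrap' or 'permutation'")

    if index == "lic":
        observed = local_index_of_collocation(zi, zj)
        num = samples @ zi
        denom = np.sqrt((samples**2).sum(axis=1) * float(zi @ zi))
        with np.errstate(invalid="ignore", divide="ignore"):
            null = np.where(denom > 0, num / denom, np.nan)
        null = null[np.isfinite(null)]
    elif index == "cooccurrence":
        observed = cooccurrence_index(zi, zj)
        both = ((samples > 0) & (zi[None, :] > 0)).sum(axis=1)
        either = ((samples > 0) | (zi[None, :] > 0)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            null = np.where(either > 0, both / either, np.nan)
        null = null[np.isfinite(null)]
    else:
        raise ValueError("index must be 'lic' or 'cooccurrence'")

    if len(null) == 0 or np.ptp(null) == 0 and np.allclose(null[0], observed):
        warnings.warn(f"{index} degenerate under resampling; p = 1", stacklevel=2)
        return RandomizationResult(index, float(observed), 1.0,
                                   float(null.mean()) if len(null) else float("nan"),
                                   n_resamples, degenerate=True)
    centre = float(null.mean())
    extreme = int((np.abs(null - centre) >= abs(observed - centre) - 1e-15).sum())
    p = (1 + extreme) / (n_resamples + 1)
    return RandomizationResult(index, float(observed), float(p), centre, n_resamples)


# --------------------------------------------------------------------------
# full table
# --------------------------------------------------------------------------


def collocation_table(
    dataset,
    pairs: list[tuple[str, str]] | None = None,
    d_along: float = 6.0,
    d_across: float = 24.0,
    min_share: float = 0.10,
    n_resamples: int = 1000,
    seed: int = 0,
    include_pooled: bool = True,
    azimuth: float = 0.0,
) -> pd.DataFrame:
    """Pairwise species collocation indices per year (plus pooled rows).

    Columns: global_overlap (inertia-ellipse IoU), patch_overlap (patch-
    ellipse-union IoU), cooccurrence, lic, mean_dominance, and randomization
    p-values for the two local indices.  Rows where an index is undefined
    (a species absent, no retained patch) carry NaN.
    """
    if pairs is None:
        sp = dataset.species
        pairs = [(sp[i], sp[j]) for i in range(len(sp)) for j in range(i + 1, len(sp))]
    rows = []
    slots: list[tuple[str, object]] = [(str(y), y) for y in dataset.years]
    if include_pooled:
        slots.append(("pooled", None))
    for si, sj in pairs:
        for label, year in slots:
            pts = dataset.points(year)
            zi = dataset.values(si, year)
            zj = dataset.values(sj, year)
            row = {"species_i": si, "species_j": sj, "year": label}
            for key in ("global_overlap", "patch_overlap", "cooccurrence", "lic",
                        "mean_dominance", "p_cooccurrence", "p_lic"):
                row[key] = np.nan
            if zi.sum() > 0 and zj.sum() > 0:
                gi, gj = inertia(pts, zi), inertia(pts, zj)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    row["global_overlap"] = ellipse_overlap(gi.ellipse, gj.ellipse)
                    row["patch_overlap"] = patch_overlap(
                        identify_patches(pts, zi, d_along, d_across, min_share, azimuth),
                        identify_patches(pts, zj, d_along, d_across, min_share, azimuth),
                    )
                    row["cooccurrence"] = cooccurrence_index(zi, zj)
                    row["lic"] = local_index_of_collocation(zi, zj)
                    dom = dominance_index(zi, zj)
                    row["mean_dominance"] = float(np.nanmean(dom))
                    key = zlib.crc32(f"{si}|{sj}|{label}".encode())
                    sub = int(np.random.SeedSequence([seed, key]).generate_state(1)[0] % 2**31)
                    row["p_cooccurrence"] = randomization_test(
                        "cooccurrence", zi, zj, n_resamples, sub).p_value
                    row["p_lic"] = randomization_test(
                        "lic", zi, zj, n_resamples, sub + 1).p_value
            rows.append(row)
    return pd.DataFrame(rows)
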