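"""Survey data model, file I/O, local projection and variable transforms.

Acoustic surveys record a biomass density (tons) for each species on every
Elementary Sampling Distance Unit (EDSU), the 1-nm along-track segment over
which backscatter is integrated.  Everything downstream (variography,
kriging, spatial indicators) works on planar coordinates in nautical miles,
obtained from WGS84 longitude/latitude by a local equirectangular projection
centred on the dataset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon


class SchemaError(ValueError):
    """A required column is missing or the column mapping is inconsistent."""


class ValidationError(ValueError):
    """The data violate a dataset invariant (negative biomass, duplicates...)."""


# --------------------------------------------------------------------------
# design and specs
# --------------------------------------------------------------------------


@dataclass
class SurveyDesign:
    """Geometry of a systematic parallel-transect acoustic survey.

    Parameters
    ----------
    n_transects : int
        Number of parallel transects.
    transect_spacing : float
        Distance between adjacent transects, nautical miles.
    edsu_length : float
        Along-transect sampling step (EDSU size), nautical miles.
    transect_azimuth : float
        Compass direction of the transects in degrees (0 = north-south
        transects, i.e. the along-transect axis is latitudinal).
    domain_polygon : shapely.Polygon
        Study-area outline in planar nm coordinates.
    grid_resolution : float
        Node spacing of the interpolation grid, nautical miles.
    """

    n_transects: int
    transect_spacing: float
    edsu_length: float
    transect_azimuth: float = 0.0
    domain_polygon: Polygon | None = None
    grid_resolution: float = 1.0

    def __post_init__(self) -> None:
        if self.transect_spacing <= 0:
            raise ValidationError("transect_spacing must be > 0")
        if self.edsu_length <= 0:
            raise ValidationError("edsu_length must be > 0")
        if self.grid_resolution <= 0:
            raise ValidationError("grid_resolution must be > 0")

    # unit vectors of the transect frame
    @property
    def along_unit(self) -> np.ndarray:
        a = math.radians(self.transect_azimuth)
        return np.array([math.sin(a), math.cos(a)])

    @property
    def across_unit(self) -> np.ndarray:
        a = math.radians(self.transect_azimuth)
        return np.array([math.cos(a), -math.sin(a)])

    def along_across(self, dx, dy):
        """Project planar separation vectors onto the (along, across) axes."""
        ua, ux = self.along_unit, self.across_unit
        return dx * ua[0] + dy * ua[1], dx * ux[0] + dy * ux[1]


@dataclass(frozen=True)
class LogTransformSpec:
    """Offset of the log transform Y = ln(B + c).

    ``c`` (tons) keeps zero-biomass EDSUs finite on the log scale; the
    conventional value is the smallest positive biomass resolved by the
    survey (0.05 tons by default), shared by every species and year so
    log-biomasses stay comparable.
    """

    c: float = 0.05

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValidationError("log-transform offset c must be > 0")


@dataclass(frozen=True)
class EdsuRecord:
    """One EDSU of one survey year, with per-species biomass densities."""

    year: int
    lon: float
    lat: float
    x: float
    y: float
    transect_id: int
    biomass: Mapping[str, float]


# --------------------------------------------------------------------------
# projection
# --------------------------------------------------------------------------


def project_to_nm(lon, lat, ref_lon: float, ref_lat: float):
    """Local equirectangular projection of WGS84 degrees to nautical miles.

    One arc-minute of latitude is one nautical mile; longitudes are scaled by
    cos(ref_lat).  Adequate over a study extent of a few degrees, and keeps
    the nm unit exact along the reference parallel.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValidationError("lon/lat outside valid WGS84 range")
    if abs(ref_lat) > 90 or abs(ref_lon) > 180:
        raise ValidationError("projection reference outside valid range")
    x = (lon - ref_lon) * 60.0 * math.cos(math.radians(ref_lat))
    y = (lat - ref_lat) * 60.0
    return x, y


def unproject_from_nm(x, y, ref_lon: float, ref_lat: float):
    """Inverse of :func:`project_to_nm`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = ref_lon + x / (60.0 * math.cos(math.radians(ref_lat)))
    lat = ref_lat + y / 60.0
    return lon, lat


# --------------------------------------------------------------------------
# transforms
# --------------------------------------------------------------------------


def log_transform(biomass, spec: LogTransformSpec = LogTransformSpec()):
    """Y = ln(B + c); strictly increasing in B, finite at B = 0."""
    b = np.asarray(biomass, dtype=float)
    if np.any(b < 0):
        raise ValidationError("biomass must be >= 0")
    return np.log(b + spec.c)


def inverse_log_transform(y, spec: LogTransformSpec = LogTransformSpec()):
    """B = exp(Y) - c, the exact inverse of :func:`log_transform`."""
    return np.exp(np.asarray(y, dtype=float)) - spec.c


def target_strength(length_cm):
    """Acoustic target strength TS = 20 log10(L) - 71.2 dB (L in cm).

    The same TS-length relation is used for anchovy, sardine and sprat.
    """
    length = np.asarray(length_cm, dtype=float)
    if np.any(length <= 0):
        raise ValidationError("fish length must be > 0")
    return 20.0 * np.log10(length) - 71.2


# --------------------------------------------------------------------------
# dataset
# --------------------------------------------------------------------------

_META_COLUMNS = ["year", "lon", "lat", "x", "y", "transect_id"]


@dataclass
class SurveyDataset:
    """Per-EDSU, multi-year, multi-species survey records.

    ``data`` holds one row per EDSU per year with columns
    ``year, lon, lat, x, y, transect_id`` plus one biomass column per species.
    """

    data: pd.DataFrame
    species: list[str]
    design: SurveyDesign | None = None
    ref_lon: float = 0.0
    ref_lat: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self.data["year"].unique())

    def validate(self) -> None:
        for col in _META_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"missing column {col!r}")
        for sp in self.species:
            if sp not in self.data.columns:
                raise SchemaError(f"missing biomass column {sp!r}")
            if (self.data[sp] < 0).any():
                raise ValidationError(f"negative biomass for species {sp!r}")
        dup = self.data.duplicated(subset=["year", "lon", "lat"])
        if dup.any():
            raise ValidationError("duplicate (year, lon, lat) records")
        counts = self.data.groupby("year").size()
        if (counts < 30).any():
            warnings.warn(
                "some survey years have fewer than 30 EDSUs; "
                "variography and kriging will be unreliable",
                stacklevel=2,
            )

    # -- access helpers -----------------------------------------------------

    def points(self, year: int | None = None) -> np.ndarray:
        df = self.data if year is None else self.data[self.data["year"] == year]
        return df[["x", "y"]].to_numpy(dtype=float)

    def values(self, species: str, year: int | None = None) -> np.ndarray:
        if species not in self.species:
            raise SchemaError(f"unknown species {species!r}")
        df = self.data if year is None else self.data[self.data["year"] == year]
        return df[species].to_numpy(dtype=float)

    def year_matrix(self, species: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (years, year x location matrix) for locations common to all
        years, matched on rounded (x, y)."""
        df = self.data.copy()
        df["_loc"] = list(zip(df["x"].round(6), df["y"].round(6)))
        pivot = df.pivot_table(index="year", columns="_loc", values=species)
        pivot = pivot.dropna(axis=1)
        return pivot.index.to_numpy(dtype=int), pivot.to_numpy(dtype=float)

    def records(self) -> Iterator[EdsuRecord]:
        for row in self.data.itertuples(index=False):
            yield EdsuRecord(
                year=int(row.year),
                lon=float(row.lon),
                lat=float(row.lat),
                x=float(row.x),
                y=float(row.y),
                transect_id=int(row.transect_id),
                biomass={sp: float(getattr(row, sp)) for sp in self.species},
            )

    def __len__(self) -> int:
        return len(self.data)


def infer_transects(across_coord: np.ndarray, gap: float = 3.0) -> np.ndarray:
    """Cluster the across-transect coordinate into transect ids.

    Samples are grouped wherever consecutive sorted across-coordinates are
    closer than ``gap`` nm; ids are numbered from the smallest coordinate.
    """
    across = np.asarray(across_coord, dtype=float)
    order = np.argsort(across)
    ids = np.zeros(len(across), dtype=int)
    current = 0
    for k in range(1, len(order)):
        if across[order[k]] - across[order[k - 1]] > gap:
            current += 1
        ids[order[k]] = current
    ids[order[0]] = 0
    return ids


def read_survey(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    sep: str | None = None,
    species: Sequence[str] | None = None,
    design: SurveyDesign | None = None,
    ref: tuple[float, float] | None = None,
    transect_gap: float = 3.0,
) -> SurveyDataset:
    """Read a delimited survey file into a validated :class:`SurveyDataset`.

    The file needs ``year``, ``lon`` and ``lat`` columns (renameable through
    ``schema``) and one biomass column per species; any non-coordinate column
    is treated as a species unless ``species`` is given.  Coordinates are
    projected locally (reference = centroid unless ``ref`` is supplied) and
    transect ids are inferred by clustering the across-transect coordinate.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items() if k in ("year", "lon", "lat")}
    df = df.rename(columns=rename)
    for col in ("year", "lon", "lat"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r}")
    if species is None:
        species = [c for c in df.columns if c not in ("year", "lon", "lat")]
    species = list(species)
    if not species:
        raise SchemaError("no biomass columns found")
    for sp in species:
        if sp not in df.columns:
            raise SchemaError(f"missing biomass column {sp!r}")

    if ref is None:
        ref = (float(df["lon"].mean()), float(df["lat"].mean()))
    ref_lon, ref_lat = ref
    x, y = project_to_nm(df["lon"].to_numpy(), df["lat"].to_numpy(), ref_lon, ref_lat)
    df = df.assign(x=x, y=y)

    azimuth = design.transect_azimuth if design is not None else 0.0
    a = math.radians(azimuth)
    across = df["x"].to_numpy() * math.cos(a) - df["y"].to_numpy() * math.sin(a)
    gap = transect_gap
    if design is not None:
        gap = min(gap, design.transect_spacing / 2.0)
    df["transect_id"] = infer_transects(across, gap=gap)

    df = df[["year", "lon", "lat", "x", "y", "transect_id", *species]]
    return SurveyDataset(
        data=df, species=species, design=design, ref_lon=ref_lon, ref_lat=ref_lat
    )


def write_survey(dataset: SurveyDataset, path) -> None:
    """Write the dataset back to CSV (year, lon, lat, one column per species).

    Floats are written in their shortest exact decimal representation so a
    read/write cycle is the identity on the stored values and dtypes.
    """
    cols = ["year", "lon", "lat", *dataset.species]
    dataset.data[cols].to_csv(path, index=False, float_format=lambda v: repr(float(v)))
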