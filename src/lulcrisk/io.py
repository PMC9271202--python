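"""Containers and file formats for raster series and site tables.

Rasters are stored as multi-page TIFF (one page per year, integer class
codes) with a JSON sidecar (``<path>.legend.json``) recording the legend,
the year index and the pixel area.  Tables are plain CSV (comma, UTF-8,
"." decimal, header required) accompanied by a ``<path>.meta.json``
sidecar carrying the schema version.

Grid convention: arrays are row-major with shape (n_years, rows, cols),
0-based indices; the year of each band is explicit in ``years``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"

#: Base land-cover classes of the gridded input maps.
BASE_CLASSES = ("forest", "pasture", "cropland", "other")
BASE_CODES = {name: i for i, name in enumerate(BASE_CLASSES)}

#: The seven analysis classes plus the residual "other" class.
#: UF/LF/LBF are degradation states of primary forest (never clear-cut),
#: SFy/SFo are young (age <= threshold) and old secondary forest,
#: PA pasture, MA mechanized agriculture.
ANALYSIS_CLASSES = ("UF", "LF", "LBF", "SFy", "SFo", "PA", "MA", "other")
ANALYSIS_CODES = {name: i for i, name in enumerate(ANALYSIS_CLASSES)}

#: Optional distinct class for fire on never-logged primary forest.
BURNED_CLASS = "BF"

SITE_TABLE_ID_COLUMNS = ("site_id", "catchment", "region", "lulc")
SITE_TABLE_COVARIATES = ("clay", "elevation", "slope")


@dataclass
class RasterSeries:
    """Annual categorical label grids.

    Parameters
    ----------
    labels : ndarray of int, shape (n_years, rows, cols)
        Per-pixel class code for each year.
    years : ndarray of int
        Calendar year of each band, strictly increasing.
    legend : dict
        Mapping ``code -> class name``.
    pixel_area_km2 : float
        Area of one pixel in km².
    """

    labels: np.ndarray
    years: np.ndarray
    legend: dict[int, str]
    pixel_area_km2: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.years = np.asarray(self.years, dtype=int)
        if self.labels.ndim != 3:
            raise ValueError("labels must have shape (n_years, rows, cols)")
        if self.labels.shape[0] != self.years.size:
            raise ValueError(
                f"band count {self.labels.shape[0]} != year count {self.years.size}"
            )
        if self.labels.shape[1] == 0 or self.labels.shape[2] == 0:
            raise ValueError("empty grid")
        if self.years.size > 1 and not np.all(np.diff(self.years) > 0):
            raise ValueError("years must be strictly increasing")
        if self.pixel_area_km2 <= 0:
            raise ValueError("pixel_area_km2 must be positive")
        known = np.isin(self.labels, list(self.legend))
        if not known.all():
            t, r, c = np.argwhere(~known)[0]
            raise ValueError(
                f"unknown label code {self.labels[t, r, c]} at pixel "
                f"({r}, {c}) in year {self.years[t]}"
            )

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.labels.shape[1], self.labels.shape[2]

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not in series ({self.years[0]}..{self.years[-1]})")
        return int(idx[0])


@dataclass
class DegradationSeries:
    """Boolean event grids (logging, fire) aligned with a RasterSeries."""

    logging: np.ndarray
    fire: np.ndarray
    years: np.ndarray

    def __post_init__(self) -> None:
        self.logging = np.asarray(self.logging, dtype=bool)
        self.fire = np.asarray(self.fire, dtype=bool)
        self.years = np.asarray(self.years, dtype=int)
        if self.logging.shape != self.fire.shape:
            raise ValueError("logging and fire grids must share a shape")
        if self.logging.shape[0] != self.years.size:
            raise ValueError("event band count != year count")


@dataclass
class ClassifiedSeries:
    """Per-pixel analysis-class labels plus the secondary-forest age counter.

    ``ages[t, r, c] > 0`` iff the pixel is secondary forest in year t; the
    counter increments by one per consecutive forest year and resets on
    clearing.  Primary forest (UF/LF/LBF) has age 0.
    """

    labels: np.ndarray
    ages: np.ndarray
    years: np.ndarray
    legend: dict[int, str]
    pixel_area_km2: float = 1.0
    age_threshold: int = 20

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.ages = np.asarray(self.ages)
        self.years = np.asarray(self.years, dtype=int)
        if self.labels.shape != self.ages.shape:
            raise ValueError("labels and ages must share a shape")

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not in series")
        return int(idx[0])


# ---------------------------------------------------------------------------
# Raster I/O (multi-page TIFF + JSON legend sidecar)
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".legend.json")


def write_raster_series(series: RasterSeries, path: str | Path) -> Path:
    """Write a raster series as a multi-page TIFF with a legend sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, series.labels.astype(np.int32), compression=None)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "years": [int(y) for y in series.years],
        "legend": {str(k): v for k, v in series.legend.items()},
        "pixel_area_km2": float(series.pixel_area_km2),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_raster_series(path: str | Path) -> RasterSeries:
    """Read a raster series written by :func:`write_raster_series`."""
    import tifffile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing legend sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    labels = tifffile.imread(path)
    if labels.ndim == 2:
        labels = labels[None]
    years = np.asarray(meta["years"], dtype=int)
    if labels.shape[0] != years.size:
        raise ValueError(
            f"band count {labels.shape[0]} != year count {years.size} in sidecar"
        )
    legend = {int(k): v for k, v in meta["legend"].items()}
    return RasterSeries(labels, years, legend, float(meta["pixel_area_km2"]))


def write_degradation_series(series: DegradationSeries, path: str | Path) -> Path:
    import tifffile

    path = Path(path)
    stacked = np.stack([series.logging, series.fire]).astype(np.uint8)
    tifffile.imwrite(path, stacked, compression=None)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "years": [int(y) for y in series.years],
        "layers": ["logging", "fire"],
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_degradation_series(path: str | Path) -> DegradationSeries:
    import tifffile

    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    stacked = tifffile.imread(path)
    years = np.asarray(meta["years"], dtype=int)
    return DegradationSeries(stacked[0].astype(bool), stacked[1].astype(bool), years)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, **meta) -> Path:
    """Write a CSV plus a ``.meta.json`` sidecar with the schema version."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(
        json.dumps({"schema_version": SCHEMA_VERSION, **meta}, indent=1, default=str)
    )
    return path


def write_site_table(df: pd.DataFrame, path: str | Path) -> Path:
    return write_table(df, path, kind="site_table")


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a site table CSV.

    Validates that mandatory identifier columns are present, every site
    belongs to exactly one catchment and every catchment to exactly one
    region.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in SITE_TABLE_ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table {path} missing columns {missing}")
    multi_catch = df.groupby("site_id")["catchment"].nunique()
    bad = multi_catch[multi_catch > 1]
    if len(bad):
        raise ValueError(f"sites in more than one catchment: {list(bad.index)[:5]}")
    dup = df["site_id"][df["site_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate site_id values: {sorted(set(dup))[:5]}")
    multi_region = df.groupby("catchment")["region"].nunique()
    bad = multi_region[multi_region > 1]
    if len(bad):
        raise ValueError(f"catchments in more than one region: {list(bad.index)[:5]}")
    return df


def dataclass_to_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(obj), indent=1, default=str))
    return path
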