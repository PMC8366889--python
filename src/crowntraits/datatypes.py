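"""Core containers shared by every stage of the pipeline.

Coordinate convention: all geometry lives in projected map coordinates
(metres).  Rasters are north-up with origin at the scene's minimum corner;
the centroid of pixel (row, col) is ``(x0 + (col + 0.5) * pixel_size,
y0 + (row + 0.5) * pixel_size)``, i.e. rows increase northward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

#: The six crown functional traits, in canonical column order.
BIOCHEMICAL_TRAITS = ("CHL", "CAR", "LWC")
ARCHITECTURAL_TRAITS = ("PAI", "FHD", "CH")
TRAITS = BIOCHEMICAL_TRAITS + ARCHITECTURAL_TRAITS

#: Ordinal coding of the eight compass aspect categories (N=1 ... NW=8).
ASPECT_LEVELS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")

#: Numeric environmental covariates.
ENV_NUMERIC = ("PAR", "elevation", "slope", "curvature")
#: Categorical environmental covariates (stored as ordinal integer codes).
ENV_CATEGORICAL = ("aspect", "soil_type", "soil_depth", "soil_rocks",
                   "understory", "herbs")
ENV_VARIABLES = ENV_NUMERIC + ENV_CATEGORICAL


class ConfigurationError(ValueError):
    """Raised for invalid generator or pipeline configuration."""


class GenerationError(RuntimeError):
    """Raised when a synthetic scene cannot be realised (e.g. packing)."""


@dataclass
class CrownRecord:
    """One delineated tree crown with taxonomy and environment."""

    crown_id: int
    species: str
    tree_class: str  # "conifer" | "angiosperm"
    polygon: Polygon
    env: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.tree_class not in ("conifer", "angiosperm"):
            raise ValueError(f"unknown tree class {self.tree_class!r}")
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError(f"crown {self.crown_id}: invalid polygon")


@dataclass
class SpectralCube:
    """Georeferenced reflectance image with per-band wavelengths (nm)."""

    reflectance: np.ndarray       # (rows, cols, bands)
    wavelengths: np.ndarray       # (bands,), nm, strictly increasing
    origin: tuple                 # (x0, y0) minimum map corner
    pixel_size: float             # metres
    nodata: float = -9999.0

    def __post_init__(self):
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.reflectance.ndim != 3:
            raise ValueError("reflectance must be (rows, cols, bands)")
        if self.reflectance.shape[2] != self.wavelengths.size:
            raise ValueError("band count must equal wavelength count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self):
        return self.reflectance.shape

    def pixel_centroids(self):
        """(x, y) map coordinates of every pixel centroid, shape (rows, cols)."""
        rows, cols, _ = self.reflectance.shape
        x0, y0 = self.origin
        x = x0 + (np.arange(cols) + 0.5) * self.pixel_size
        y = y0 + (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    def band_index(self, wavelength_nm: float, tol: float = 10.0) -> int:
        """Nearest band to ``wavelength_nm`` within ``tol`` nm.

        Raises ``KeyError`` naming the band when no band is close enough.
        """
        i = int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))
        if abs(self.wavelengths[i] - wavelength_nm) > tol:
            raise KeyError(
                f"no band within {tol} nm of {wavelength_nm} nm "
                f"(nearest: {self.wavelengths[i]:.1f} nm)")
        return i


@dataclass
class PointCloud:
    """Terrain-normalised lidar returns."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray                 # height above terrain, m
    is_ground: np.ndarray         # bool
    crown_id: np.ndarray | None = None   # -1 = unassigned

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.is_ground = np.asarray(self.is_ground, dtype=bool)
        n = self.x.size
        if not (self.y.size == self.z.size == self.is_ground.size == n):
            raise ValueError("point cloud arrays must have equal length")
        if n and self.z.min() < -0.5:
            raise ValueError("height above terrain below -0.5 m tolerance")
        if self.crown_id is not None:
            self.crown_id = np.asarray(self.crown_id, dtype=int)

    def __len__(self):
        return self.x.size

    def subset(self, mask: np.ndarray) -> "PointCloud":
        cid = self.crown_id[mask] if self.crown_id is not None else None
        return PointCloud(self.x[mask], self.y[mask], self.z[mask],
                          self.is_ground[mask], cid)


@dataclass
class Spectrum:
    """Crown-mean reflectance with its wavelength grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    n_pixels_used: int = 0

    def band(self, wavelength_nm: float, tol: float = 10.0) -> float:
        i = int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))
        if abs(self.wavelengths[i] - wavelength_nm) > tol:
            raise KeyError(
                f"no band within {tol} nm of {wavelength_nm} nm")
        return float(self.reflectance[i])


@dataclass
class EnvRasters:
    """Co-registered per-pixel environmental covariate layers.

    ``layers`` maps variable name -> 2-D array on the same grid; categorical
    layers hold ordinal integer codes (see :data:`ASPECT_LEVELS` etc.).
    """

    layers: dict
    origin: tuple
    pixel_size: float

    def __post_init__(self):
        shapes = {v.shape for v in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError("environmental layers must share one grid")

    @property
    def grid_shape(self):
        return next(iter(self.layers.values())).shape

    def pixel_centroids(self):
        rows, cols = self.grid_shape
        x0, y0 = self.origin
        x = x0 + (np.arange(cols) + 0.5) * self.pixel_size
        y = y0 + (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)


def empty_trait_table(crown_ids) -> pd.DataFrame:
    """TraitTable skeleton: one row per crown, NaN = explicit missing."""
    df = pd.DataFrame(index=pd.Index(crown_ids, name="crown_id"),
                      columns=list(TRAITS), dtype=float)
    df["n_pixels_used"] = 0
    df["n_returns_used"] = 0
    return df


def validate_trait_table(table: pd.DataFrame) -> None:
    for t in TRAITS:
        if t not in table.columns:
            raise ValueError(f"trait table missing column {t}")
    for t in ("CH", "PAI", "FHD"):
        vals = table[t].dropna()
        if (vals < 0).any():
            raise ValueError(f"{t} must be non-negative")
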