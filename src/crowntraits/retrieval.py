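"""Per-crown functional trait retrieval.

Three biochemical traits come from narrow-band indices on the shadow-masked
crown-mean reflectance spectrum:

* ``CHL`` — red-edge normalised difference, (R750 − R705)/(R750 + R705)
* ``CAR`` — reciprocal-reflectance difference, 1/R510 − 1/R550
* ``LWC`` — normalised difference water index on two NIR bands,
  (R860 − R1240)/(R860 + R1240)

Three architectural traits come from the terrain-normalised point cloud:

* ``CH``  — maximum non-ground return height in the crown (m)
* ``PAI`` — Beer–Lambert inversion of the lidar gap fraction,
  −ln(gap)/k with gap = fraction of returns below a ground cutoff
* ``FHD`` — Shannon entropy (nats) of the non-ground return counts in 5-m
  height layers

The index registry is a plain dict so alternative band formulae can be
dropped in without touching the pipeline.
"""

from __future__ import annotations

import warnings

import numpy as np
import shapely
from shapely.strtree import STRtree

from .datatypes import (ENV_CATEGORICAL, CrownRecord, EnvRasters,
                        PointCloud, SpectralCube, Spectrum,
                        empty_trait_table)

# defaults pinned by the processing configuration
SHADOW_NIR_WINDOW = (780.0, 850.0)   # nm
SHADOW_THRESHOLD = 0.15              # mean NIR reflectance
PAI_K = 0.5                          # extinction coefficient
PAI_GROUND_CUTOFF = 2.0              # m
PAI_MIN_RETURNS = 10
FHD_LAYER_HEIGHT = 5.0               # m
BAND_TOL = 10.0                      # nm, nearest-band lookup tolerance


# ---------------------------------------------------------------- spectra

def shadow_mask(cube: SpectralCube,
                nir_threshold: float = SHADOW_THRESHOLD) -> np.ndarray:
    """Boolean keep-mask: True where the pixel is considered sun-lit.

    A pixel is dropped iff its mean reflectance over 780-850 nm falls below
    ``nir_threshold``.
    """
    lo, hi = SHADOW_NIR_WINDOW
    sel = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
    if not sel.any():
        raise ValueError(f"cube has no bands in {lo}-{hi} nm; "
                         "cannot build a shadow mask")
    nir_mean = cube.reflectance[:, :, sel].mean(axis=2)
    return nir_mean >= nir_threshold


def pixels_in_crown(cube, crown: CrownRecord):
    """(rows, cols) of pixels whose centroid lies inside or on the crown.

    Works for a :class:`SpectralCube` or :class:`EnvRasters` alike (anything
    with ``pixel_centroids()``).  An empty selection is returned silently;
    callers decide whether that is a warning or a missing-trait condition.
    """
    xx, yy = cube.pixel_centroids()
    poly = crown.polygon
    minx, miny, maxx, maxy = poly.bounds
    cand = (xx >= minx) & (xx <= maxx) & (yy >= miny) & (yy <= maxy)
    rows, cols = np.nonzero(cand)
    if rows.size == 0:
        return rows, cols
    pts = shapely.points(xx[rows, cols], yy[rows, cols])
    inside = shapely.covers(poly, pts)   # covers: interior + boundary
    return rows[inside], cols[inside]


def crown_mean_reflectance(cube: SpectralCube, crown: CrownRecord,
                           mask: np.ndarray | None = None) -> Spectrum | None:
    """Per-band arithmetic mean over unmasked pixels inside the crown.

    Returns None when no unmasked pixel falls inside the crown (the crown is
    then flagged missing for the biochemical traits).
    """
    rows, cols = pixels_in_crown(cube, crown)
    if mask is not None and rows.size:
        keep = mask[rows, cols]
        rows, cols = rows[keep], cols[keep]
    if rows.size == 0:
        return None
    mean = cube.reflectance[rows, cols, :].mean(axis=0)
    return Spectrum(cube.wavelengths, mean, n_pixels_used=int(rows.size))


def chl_index(spectrum: Spectrum) -> float:
    """Red-edge normalised difference chlorophyll index."""
    r750, r705 = spectrum.band(750.0), spectrum.band(705.0)
    denom = r750 + r705
    if denom <= 0:
        return float("nan")
    return (r750 - r705) / denom


def car_index(spectrum: Spectrum) -> float:
    """Reciprocal-reflectance carotenoid index, 1/R510 - 1/R550."""
    r510, r550 = spectrum.band(510.0), spectrum.band(550.0)
    if r510 <= 0 or r550 <= 0:
        return float("nan")
    return 1.0 / r510 - 1.0 / r550


def lwc_index(spectrum: Spectrum) -> float:
    """Normalised difference water index on the 860/1240 nm NIR bands."""
    r860, r1240 = spectrum.band(860.0), spectrum.band(1240.0)
    denom = r860 + r1240
    if denom <= 0:
        return float("nan")
    return (r860 - r1240) / denom


#: name -> callable(Spectrum) -> float; replace entries to change formulae.
INDEX_REGISTRY = {"CHL": chl_index, "CAR": car_index, "LWC": lwc_index}

#: wavelengths each default index needs (used by the forward model).
INDEX_BANDS = {"CHL": (750.0, 705.0), "CAR": (510.0, 550.0),
               "LWC": (860.0, 1240.0)}


# ------------------------------------------------------------- point cloud

def canopy_height(points: PointCloud,
                  percentile: float | None = None) -> float:
    """Height above terrain of the crown top (m).

    Default is the maximum non-ground return; ``percentile`` (e.g. 99)
    switches to a robust upper quantile of the non-ground heights.
    """
    z = points.z[~points.is_ground]
    if z.size == 0:
        return float("nan")
    if percentile is not None:
        return float(np.percentile(z, percentile))
    return float(z.max())


def plant_area_index(points: PointCloud, k: float = PAI_K,
                     ground_cutoff: float = PAI_GROUND_CUTOFF,
                     min_returns: int = PAI_MIN_RETURNS) -> float:
    """Beer–Lambert PAI from the lidar gap fraction.

    gap = (returns below ``ground_cutoff``)/total, floored at 1/(2·total) so
    a fully closed canopy yields a finite estimate.
    """
    n = len(points)
    if n < min_returns:
        return float("nan")
    gap = np.count_nonzero(points.z < ground_cutoff) / n
    eps = 1.0 / (2.0 * n)
    return float(-np.log(max(gap, eps)) / k)


def foliage_height_diversity(points: PointCloud,
                             layer_height: float = FHD_LAYER_HEIGHT) -> float:
    """Shannon entropy of non-ground returns binned in 5-m height layers."""
    z = points.z[~points.is_ground]
    if z.size == 0:
        return float("nan")
    top = z.max()
    n_layers = max(1, int(np.ceil(top / layer_height)))
    idx = np.minimum((z / layer_height).astype(int), n_layers - 1)
    counts = np.bincount(idx, minlength=n_layers)
    p = counts[counts > 0] / z.size
    return float(-(p * np.log(p)).sum())


def assign_points_to_crowns(cloud: PointCloud,
                            crowns: list[CrownRecord]) -> PointCloud:
    """Label each return with the crown polygon that contains it.

    Points inside several (overlapping) crowns go to the crown with the
    nearest centroid; points in no crown get -1.
    """
    tree = STRtree([c.polygon for c in crowns])
    pts = shapely.points(cloud.x, cloud.y)
    pt_idx, poly_idx = tree.query(pts, predicate="intersects")
    crown_id = np.full(len(cloud), -1, dtype=int)
    if pt_idx.size:
        cx = np.array([c.polygon.centroid.x for c in crowns])
        cy = np.array([c.polygon.centroid.y for c in crowns])
        d2 = ((cloud.x[pt_idx] - cx[poly_idx]) ** 2
              + (cloud.y[pt_idx] - cy[poly_idx]) ** 2)
        order = np.lexsort((d2, pt_idx))   # per point: nearest crown first
        pt_sorted = pt_idx[order]
        first = np.ones(pt_sorted.size, dtype=bool)
        first[1:] = pt_sorted[1:] != pt_sorted[:-1]
        ids = np.array([c.crown_id for c in crowns])
        crown_id[pt_sorted[first]] = ids[poly_idx[order][first]]
    return PointCloud(cloud.x, cloud.y, cloud.z, cloud.is_ground, crown_id)


# ------------------------------------------------------------ environment

def _lower_median(codes: np.ndarray) -> int:
    """Median of ordinal codes; even counts resolve to the lower middle."""
    s = np.sort(codes)
    return int(s[(s.size - 1) // 2])


def assign_env_to_crowns(env: EnvRasters, crowns: list[CrownRecord],
                         categorical=ENV_CATEGORICAL) -> list[CrownRecord]:
    """Fill each crown's env dict from the pixels inside its polygon.

    Numeric variables take the mean over pixel centroids inside the polygon;
    categorical variables the (lower-tie) median of their ordinal codes.
    Crowns containing no pixel centroid fall back to the nearest pixel, with
    a warning.
    """
    xx, yy = env.pixel_centroids()
    for crown in crowns:
        rows, cols = pixels_in_crown(env, crown)
        if rows.size == 0:
            cx, cy = crown.polygon.centroid.x, crown.polygon.centroid.y
            flat = np.argmin((xx - cx) ** 2 + (yy - cy) ** 2)
            rows, cols = np.unravel_index([flat], xx.shape)
            warnings.warn(f"crown {crown.crown_id}: no pixel centroid "
                          "inside polygon; nearest-pixel fallback")
        for name, layer in env.layers.items():
            vals = layer[rows, cols]
            if name in categorical:
                crown.env[name] = _lower_median(np.asarray(vals, dtype=int))
            else:
                crown.env[name] = float(np.mean(vals))
        crown.env["n_env_pixels"] = int(rows.size)
    return crowns


# -------------------------------------------------------------- end to end

def retrieve_traits(cube: SpectralCube, cloud: PointCloud,
                    crowns: list[CrownRecord],
                    nir_threshold: float = SHADOW_THRESHOLD,
                    index_registry: dict | None = None,
                    k: float = PAI_K,
                    ground_cutoff: float = PAI_GROUND_CUTOFF,
                    min_returns: int = PAI_MIN_RETURNS,
                    layer_height: float = FHD_LAYER_HEIGHT):
    """Full retrieval stage: TraitTable (one row per crown) plus spectra.

    Returns ``(table, spectra, log)`` where ``spectra`` maps crown_id to the
    crown-mean :class:`Spectrum` (None when fully shadow-masked) and ``log``
    records per-crown exclusion reasons.
    """
    registry = dict(INDEX_REGISTRY if index_registry is None
                    else index_registry)
    mask = shadow_mask(cube, nir_threshold)
    if cloud.crown_id is None:
        cloud = assign_points_to_crowns(cloud, crowns)
    table = empty_trait_table([c.crown_id for c in crowns])
    spectra: dict[int, Spectrum | None] = {}
    log: dict[int, list] = {c.crown_id: [] for c in crowns}

    for crown in crowns:
        cid = crown.crown_id
        spec = crown_mean_reflectance(cube, crown, mask)
        spectra[cid] = spec
        if spec is None:
            log[cid].append("no unmasked pixels: biochemical traits missing")
        else:
            table.loc[cid, "n_pixels_used"] = spec.n_pixels_used
            for trait, fn in registry.items():
                val = fn(spec)
                table.loc[cid, trait] = val
                if np.isnan(val):
                    log[cid].append(f"{trait}: invalid band reflectance")
        in_crown = cloud.subset(cloud.crown_id == cid)
        table.loc[cid, "n_returns_used"] = len(in_crown)
        if len(in_crown) == 0:
            log[cid].append("no lidar returns: architectural traits missing")
            continue
        table.loc[cid, "CH"] = canopy_height(in_crown)
        table.loc[cid, "PAI"] = plant_area_index(in_crown, k, ground_cutoff,
                                                 min_returns)
        table.loc[cid, "FHD"] = foliage_height_diversity(in_crown,
                                                         layer_height)
        for t in ("CH", "PAI", "FHD"):
            if np.isnan(table.loc[cid, t]):
                log[cid].append(f"{t}: below minimum return count")
    return table, spectra, log
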