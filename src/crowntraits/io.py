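"""Readers and writers for every artifact the pipeline produces.

Formats: crowns as GeoJSON; spectral cube as ENVI (flat band-sequential
float32 binary + text ``.hdr`` carrying wavelengths and the map origin /
pixel size); point cloud as CSV (x, y, z = height above ground, is_ground,
optional crown_id); trait tables as CSV with explicit NA; environmental
rasters as compressed ``.npz``; generator configs as YAML.  Every writer
has a matching reader and round-trips bit-exactly where the format allows.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import shape as shapely_shape, mapping

from .datatypes import CrownRecord, EnvRasters, PointCloud, SpectralCube
from .simulate import SimConfig, SpeciesSpec


# ------------------------------------------------------------------ crowns

def save_crowns_geojson(crowns, path) -> None:
    features = []
    for c in crowns:
        props = {"crown_id": c.crown_id, "species": c.species,
                 "tree_class": c.tree_class}
        props.update(c.env)
        features.append({"type": "Feature", "geometry": mapping(c.polygon),
                         "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def load_crowns_geojson(path) -> list:
    with open(path) as fh:
        data = json.load(fh)
    crowns = []
    for feat in data["features"]:
        props = dict(feat["properties"])
        crowns.append(CrownRecord(
            crown_id=props.pop("crown_id"),
            species=props.pop("species"),
            tree_class=props.pop("tree_class"),
            polygon=shapely_shape(feat["geometry"]),
            env=props))
    return crowns


# ------------------------------------------------------------------- cube

def save_cube_envi(cube: SpectralCube, path) -> None:
    """ENVI BSQ float32 with a text header (``<path>.hdr``)."""
    path = Path(path)
    arr = np.ascontiguousarray(
        np.moveaxis(cube.reflectance.astype(np.float32), 2, 0))  # band-major
    arr.tofile(path)
    rows, cols, bands = cube.shape
    x0, y0 = cube.origin
    hdr = [
        "ENVI",
        f"samples = {cols}", f"lines = {rows}", f"bands = {bands}",
        "header offset = 0", "file type = ENVI Standard",
        "data type = 4", "interleave = bsq", "byte order = 0",
        f"map info = {{Arbitrary, 1, 1, {x0}, {y0}, "
        f"{cube.pixel_size}, {cube.pixel_size}}}",
        "wavelength units = Nanometers",
        "wavelength = {" + ", ".join(f"{w:.4f}"
                                     for w in cube.wavelengths) + "}",
    ]
    path.with_suffix(path.suffix + ".hdr").write_text("\n".join(hdr) + "\n")


def _parse_envi_header(text: str) -> dict:
    out, key, buf = {}, None, ""
    for raw in text.splitlines():
        line = raw.strip()
        if key is not None:                  # inside a braced value
            buf += " " + line
            if "}" in line:
                out[key] = buf.split("{", 1)[1].rsplit("}", 1)[0].strip()
                key = None
            continue
        if "=" not in line:
            continue
        k, v = (s.strip() for s in line.split("=", 1))
        if v.startswith("{") and "}" not in v:
            key, buf = k.lower(), v
        elif v.startswith("{"):
            out[k.lower()] = v.split("{", 1)[1].rsplit("}", 1)[0].strip()
        else:
            out[k.lower()] = v
    return out


def load_cube_envi(path) -> SpectralCube:
    path = Path(path)
    hdr = _parse_envi_header(
        path.with_suffix(path.suffix + ".hdr").read_text())
    rows = int(hdr["lines"])
    cols = int(hdr["samples"])
    bands = int(hdr["bands"])
    if hdr.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    wl = np.array([float(w) for w in hdr["wavelength"].split(",")])
    map_info = [s.strip() for s in hdr["map info"].split(",")]
    x0, y0, px = float(map_info[3]), float(map_info[4]), float(map_info[5])
    data = np.fromfile(path, dtype=np.float32).reshape(bands, rows, cols)
    return SpectralCube(np.moveaxis(data, 0, 2).astype(float), wl,
                        origin=(x0, y0), pixel_size=px)


# ------------------------------------------------------------- point cloud

def save_pointcloud_csv(cloud: PointCloud, path) -> None:
    df = pd.DataFrame({"x": cloud.x, "y": cloud.y,
                       "height_above_ground": cloud.z,
                       "is_ground": cloud.is_ground.astype(int)})
    if cloud.crown_id is not None:
        df["crown_id"] = cloud.crown_id
    df.to_csv(path, index=False)


def load_pointcloud_csv(path) -> PointCloud:
    df = pd.read_csv(path)
    cid = df["crown_id"].to_numpy() if "crown_id" in df.columns else None
    return PointCloud(df["x"].to_numpy(), df["y"].to_numpy(),
                      df["height_above_ground"].to_numpy(),
                      df["is_ground"].to_numpy().astype(bool), cid)


# ------------------------------------------------------------ trait tables

def save_trait_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, na_rep="NA")


def load_trait_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="crown_id", na_values=["NA"])


# ------------------------------------------------------------- env rasters

def save_env_rasters(env: EnvRasters, path) -> None:
    np.savez_compressed(path, origin=np.array(env.origin),
                        pixel_size=np.array([env.pixel_size]),
                        **env.layers)


def load_env_rasters(path) -> EnvRasters:
    with np.load(path) as data:
        origin = tuple(data["origin"])
        px = float(data["pixel_size"][0])
        layers = {k: data[k] for k in data.files
                  if k not in ("origin", "pixel_size")}
    return EnvRasters(layers, origin, px)


# ------------------------------------------------------------------ config

def _plain(obj):
    """Recursively convert numpy scalars/arrays to builtin types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def config_to_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["species_table"] = [dataclasses.asdict(s) for s in cfg.species_table]
    return _plain(d)


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["species_table"] = [SpeciesSpec(**s) for s in d["species_table"]]
    for key in ("scene_extent", "crown_radius_bounds"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    cfg = SimConfig(**d)
    cfg.validate()
    return cfg


def save_config(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> SimConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
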