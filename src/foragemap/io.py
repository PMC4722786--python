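"""File formats: trajectory CSV, raster TIFF + JSON sidecar, GeoJSON vectors.

Rasters are plain multi-band TIFFs (band-major) with a JSON sidecar holding
the band wavelengths, grid geometry and provenance, since the analysis
works in a local planar CRS throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping, shape


# ---------------------------------------------------------------------------
# trajectories


def write_trajectory_csv(traj: pd.DataFrame, path) -> None:
    """CSV with columns id, timestamp (ISO-8601 UTC), x, y."""
    out = pd.DataFrame(
        {
            "id": traj["id"],
            "timestamp": pd.to_datetime(traj["t"], utc=True).dt.strftime(
                "%Y-%m-%dT%H:%M:%SZ"
            ),
            "x": traj["x"],
            "y": traj["y"],
        }
    )
    for col in ("flag_stage1", "flag_stage2"):
        if col in traj.columns:
            out[col] = traj[col]
    out.to_csv(path, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    out = pd.DataFrame(
        {
            "id": df["id"],
            "t": pd.to_datetime(df["timestamp"], utc=True),
            "x": df["x"].astype(float),
            "y": df["y"].astype(float),
        }
    )
    for col in ("flag_stage1", "flag_stage2"):
        if col in df.columns:
            out[col] = df[col].astype(bool)
    return out


# ---------------------------------------------------------------------------
# rasters


def write_cube(cube: np.ndarray, path, wavelengths=None, cell_size: float = 2.0,
               origin=(0.0, 0.0), **extra) -> None:
    """Multi-band TIFF plus a ``<path>.json`` sidecar with grid metadata."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(cube, dtype=np.float32),
                     photometric="minisblack", planarconfig="separate")
    sidecar = {
        "wavelengths_nm": list(map(float, wavelengths)) if wavelengths is not None else None,
        "cell_size_m": cell_size,
        "origin": list(origin),
        **extra,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_cube(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    cube = tifffile.imread(path).astype(float)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return cube, sidecar


def write_resource_raster(raster, path, **extra) -> None:
    """2-band TIFF (biomass, nitrogen; NaN = no data) + sidecar."""
    stack = np.stack(
        [
            raster.layer("biomass").astype(np.float32),
            raster.layer("nitrogen").astype(np.float32),
        ]
    )
    write_cube(stack, path, wavelengths=None, cell_size=raster.cell_size,
               origin=raster.origin, layers=["biomass_g_m2", "nitrogen_pct"],
               nodata="nan", **extra)


# ---------------------------------------------------------------------------
# vectors


def write_polygons_geojson(polygons: dict, path, **extra_props) -> None:
    """FeatureCollection with one feature per (label -> geometry) entry."""
    features = []
    for label, geom in polygons.items():
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {"label": label, **extra_props},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_polygons_geojson(path) -> dict:
    doc = json.loads(Path(path).read_text())
    return {
        f["properties"].get("label", str(k)): shape(f["geometry"])
        for k, f in enumerate(doc["features"])
    }


def write_endmember_library_csv(library: np.ndarray, labels, path) -> None:
    df = pd.DataFrame(np.asarray(library), index=list(labels))
    df.index.name = "label"
    df.to_csv(path)


def read_endmember_library_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col="label")
    return df.to_numpy(dtype=float), list(df.index)
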