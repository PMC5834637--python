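"""File-format helpers: CSV point tables, TIFF rasters, GeoJSON, configs.

Rasters are written as plain TIFF with a small JSON sidecar
(``<name>.tif.json``) carrying the georeferencing (gsd, origin, island id);
point tables are CSV; polygons and point sets can be exported as GeoJSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detection import DetectionSet
from .synthetic import ColonyLayout, Orthomosaic

__all__ = [
    "write_layout_csv", "read_points_csv",
    "write_detections_csv", "read_detections_csv",
    "write_raster", "read_raster",
    "detections_to_geojson",
    "write_yaml", "read_yaml",
]


def write_layout_csv(path, layout: ColonyLayout,
                     artifact_points: np.ndarray | None = None) -> None:
    """Truth points CSV: island_id, subcolony_id, x_m, y_m, class."""
    rows = [
        {"island_id": layout.island_id, "subcolony_id": int(sc),
         "x_m": x, "y_m": y, "class": "nest"}
        for (x, y), sc in zip(layout.nests, layout.subcolony_id)
    ]
    if artifact_points is not None:
        rows += [
            {"island_id": layout.island_id, "subcolony_id": -1,
             "x_m": x, "y_m": y, "class": "artifact"}
            for x, y in np.asarray(artifact_points).reshape(-1, 2)
        ]
    pd.DataFrame(rows, columns=["island_id", "subcolony_id",
                                "x_m", "y_m", "class"]).to_csv(path, index=False)


def read_points_csv(path, cls: str | None = None) -> np.ndarray:
    df = pd.read_csv(path)
    if cls is not None:
        df = df[df["class"] == cls]
    return df[["x_m", "y_m"]].to_numpy(dtype=float)


def write_detections_csv(path, det: DetectionSet) -> None:
    pd.DataFrame({
        "x_m": det.points[:, 0], "y_m": det.points[:, 1], "score": det.scores,
    }).to_csv(path, index=False)


def read_detections_csv(path, raster_id: str = "") -> DetectionSet:
    df = pd.read_csv(path)
    return DetectionSet(df[["x_m", "y_m"]].to_numpy(dtype=float),
                        df["score"].to_numpy(dtype=float), raster_id)


def write_raster(path, ortho: Orthomosaic) -> None:
    path = Path(path)
    tifffile.imwrite(path, ortho.pixels.astype(np.float32))
    sidecar = {"gsd": ortho.gsd, "origin": list(ortho.origin),
               "island_id": ortho.island_id}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_raster(path) -> Orthomosaic:
    path = Path(path)
    pixels = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return Orthomosaic(pixels, meta["gsd"], tuple(meta["origin"]),
                       meta.get("island_id", ""))


def detections_to_geojson(det: DetectionSet) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature",
             "geometry": {"type": "Point", "coordinates": [x, y]},
             "properties": {"score": float(s)}}
            for (x, y), s in zip(det.points, det.scores)
        ],
    }


def write_yaml(path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())
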