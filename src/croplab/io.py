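"""Disk formats: index rasters (TIFF), complex stacks, field polygons (GeoJSON).

Rasters are written as TIFF with a JSON description tag carrying the index
name, DOY, affine transform, and CRS identifier; single-band float32 with
nodata -9999 for index rasters, two-band complex64 for scattering stacks.
Field polygons travel as GeoJSON with ``field_id``, ``class_label``, and
``partition`` properties; acquisition dates as a two-column CSV
(filename, doy).
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape

from croplab.polarimetry import NODATA, IndexRaster
from croplab.timeseries import FieldPolygon

__all__ = [
    "write_index_raster",
    "read_index_raster",
    "write_index_stack",
    "read_index_stack",
    "write_scene_stacks",
    "read_scene_stacks",
    "write_fields_geojson",
    "read_fields_geojson",
    "write_dates_csv",
    "read_dates_csv",
]


def _meta_json(index_name: str, doy: int, transform, crs) -> str:
    return json.dumps(
        {"index_name": index_name, "doy": int(doy),
         "transform": list(transform), "crs": crs, "nodata": NODATA}
    )


def write_index_raster(path, raster: IndexRaster) -> Path:
    """Single-band float32 TIFF, NaN encoded as the nodata value."""
    path = Path(path)
    values = np.where(np.isnan(raster.values), NODATA, raster.values).astype(np.float32)
    tifffile.imwrite(
        path, values,
        description=_meta_json(raster.index_name, raster.doy, raster.transform, raster.crs),
    )
    return path


def read_index_raster(path) -> IndexRaster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        meta = json.loads(page.description)
    values[values == meta.get("nodata", NODATA)] = np.nan
    return IndexRaster(
        values=values,
        index_name=meta["index_name"],
        doy=int(meta["doy"]),
        transform=tuple(meta.get("transform", (0.0, 1.0, 0.0, 1.0))),
        crs=meta.get("crs"),
    )


def write_index_stack(out_dir, rasters: Iterable[IndexRaster]) -> list[Path]:
    """One file per date, named ``<index>_doy<DOY>.tif``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return [
        write_index_raster(out_dir / f"{r.index_name}_doy{r.doy:03d}.tif", r) for r in rasters
    ]


def read_index_stack(in_dir) -> list[IndexRaster]:
    paths = sorted(Path(in_dir).glob("*_doy*.tif"))
    if not paths:
        raise FileNotFoundError(f"no index rasters (*_doyNNN.tif) in {in_dir}")
    return sorted((read_index_raster(p) for p in paths), key=lambda r: r.doy)


def write_scene_stacks(out_dir, stacks, doys: Sequence[int]) -> list[Path]:
    """Per-date two-band complex64 TIFFs (band 0 = S_VV, band 1 = S_VH)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (vv, vh), doy in zip(stacks, doys):
        path = out_dir / f"slc_doy{doy:03d}.tif"
        data = np.stack([vv, vh]).astype(np.complex64)
        tifffile.imwrite(path, data, description=json.dumps({"doy": int(doy)}))
        paths.append(path)
    return paths


def read_scene_stacks(in_dir) -> tuple[list, list[int]]:
    """Read per-date complex stacks; returns ([(vv, vh), ...], [doy, ...])."""
    paths = sorted(Path(in_dir).glob("slc_doy*.tif"))
    if not paths:
        raise FileNotFoundError(f"no complex stacks (slc_doyNNN.tif) in {in_dir}")
    stacks, doys = [], []
    for p in paths:
        data = tifffile.imread(p)
        stacks.append((data[0].astype(complex), data[1].astype(complex)))
        doys.append(int(re.search(r"doy(\d+)", p.stem).group(1)))
    order = np.argsort(doys)
    return [stacks[i] for i in order], [doys[i] for i in order]


def write_fields_geojson(path, fields: Iterable[FieldPolygon]) -> Path:
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "geometry": geom_mapping(f.geometry),
            "properties": {
                "field_id": f.field_id,
                "class_label": f.class_label,
                "partition": f.partition,
            },
        }
        for f in fields
    ]
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def read_fields_geojson(path) -> list[FieldPolygon]:
    payload = json.loads(Path(path).read_text())
    fields = []
    for feat in payload["features"]:
        props = feat["properties"]
        fields.append(
            FieldPolygon(
                field_id=str(props["field_id"]),
                class_label=str(props["class_label"]),
                geometry=geom_shape(feat["geometry"]),
                partition=str(props.get("partition", "train")),
            )
        )
    return fields


def write_dates_csv(path, filenames: Sequence[str], doys: Sequence[int]) -> Path:
    path = Path(path)
    pd.DataFrame({"filename": filenames, "doy": doys}).to_csv(path, index=False)
    return path


def read_dates_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if not {"filename", "doy"} <= set(frame.columns):
        raise ValueError("dates CSV needs columns: filename, doy")
    return frame
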