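"""Readers and writers for the on-disk formats the pipeline exchanges:
TIFF slides, GeoJSON nucleus polygons, MTX-triplet bin counts with a parquet
tissue-positions table, and h5ad matrices."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.parquet as pq
import scipy.io as sio
import scipy.sparse as sp
import tifffile

from .expression import BinTable
from .geometry import NucleusPolygon, SlideImage


def write_slide_tiff(image: SlideImage, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, image.pixels,
                     description=json.dumps({"um_per_px": image.um_per_px,
                                             "name": image.name}))
    return path


def read_slide_tiff(path, um_per_px: float | None = None) -> SlideImage:
    """Read an RGB TIFF. The physical scale comes from the JSON image
    description written by :func:`write_slide_tiff`, or from ``um_per_px``
    for third-party files."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pixels = tf.asarray()
        desc = tf.pages[0].description
    name = path.stem
    if um_per_px is None:
        try:
            meta = json.loads(desc)
            um_per_px = float(meta["um_per_px"])
            name = meta.get("name", name)
        except (TypeError, ValueError, KeyError) as exc:
            raise ValueError(
                f"{path} carries no um_per_px metadata; pass um_per_px explicitly"
            ) from exc
    return SlideImage(pixels=pixels, um_per_px=um_per_px, name=name)


def write_polygons_geojson(polygons: list[NucleusPolygon], path) -> Path:
    """GeoJSON FeatureCollection in slide pixel coordinates with a
    ``cell_id`` property per feature."""
    path = Path(path)
    features = []
    for p in polygons:
        ring = p.vertices.tolist()
        if ring[0] != ring[-1]:
            ring = ring + [ring[0]]
        features.append({
            "type": "Feature",
            "properties": {"cell_id": p.cell_id},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def read_polygons_geojson(path) -> list[NucleusPolygon]:
    data = json.loads(Path(path).read_text())
    polygons = []
    for k, feat in enumerate(data["features"]):
        ring = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)
        if np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        cell_id = feat.get("properties", {}).get("cell_id", f"cell_{k:05d}")
        polygons.append(NucleusPolygon(cell_id=cell_id, vertices=ring))
    return polygons


def write_bin_table(bins: BinTable, directory) -> dict[str, Path]:
    """MTX triplet (counts, barcodes, features) plus a parquet positions table
    with columns barcode / row / col giving bin-center pixel coordinates."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "matrix.mtx",
        "barcodes": directory / "barcodes.tsv",
        "features": directory / "features.tsv",
        "positions": directory / "tissue_positions.parquet",
    }
    sio.mmwrite(paths["matrix"], bins.counts.astype(np.int64))
    paths["barcodes"].write_text("\n".join(bins.barcodes) + "\n")
    paths["features"].write_text("\n".join(bins.genes) + "\n")
    table = pa.table({
        "barcode": bins.barcodes,
        "row": bins.bin_centers[:, 1],
        "col": bins.bin_centers[:, 0],
    })
    pq.write_table(table, paths["positions"])
    return paths


def read_bin_table(directory) -> BinTable:
    directory = Path(directory)
    counts = sp.csr_matrix(sio.mmread(directory / "matrix.mtx"))
    barcodes = (directory / "barcodes.tsv").read_text().splitlines()
    genes = (directory / "features.tsv").read_text().splitlines()
    pos = pq.read_table(directory / "tissue_positions.parquet").to_pandas()
    pos = pos.set_index("barcode").loc[barcodes]
    centers = np.column_stack([pos["col"].to_numpy(), pos["row"].to_numpy()])
    return BinTable(barcodes=barcodes, genes=genes, counts=counts,
                    bin_centers=centers)


def positions_frame(bins: BinTable) -> pd.DataFrame:
    return pd.DataFrame({"barcode": bins.barcodes,
                         "row": bins.bin_centers[:, 1],
                         "col": bins.bin_centers[:, 0]})
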