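"""File I/O: probability-map rasters, binary masks, GeoJSON annotations,
detection tables, and sample manifests.

Grayscale probability encodings divide by the maximum representable
integer (255 or 65535), so a full-scale pixel decodes to exactly 1.0.
The ``array`` encoding is NumPy ``.npy`` and round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import shapely
import tifffile
from PIL import Image
from shapely.geometry import shape as shapely_shape

from .types import Box, BinaryMask, DetectionSet, ProbabilityMap, SampleRecord

ENCODINGS = ("gray8", "gray16", "array")
_MAXVAL = {"gray8": 255, "gray16": 65535}


def _read_raster(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    with Image.open(path) as im:
        return np.asarray(im)


def _write_raster(path: Path, arr: np.ndarray) -> None:
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def read_probability_map(
    path: str | Path,
    encoding: str,
    pixel_size_um: float = 0.23,
    sample_id: str = "",
) -> ProbabilityMap:
    """Read a probability map from a raster or ``.npy`` file.

    Parameters
    ----------
    encoding
        ``gray8``/``gray16``: integer grayscale raster rescaled by the max
        representable value; ``array``: a float ``.npy`` already in [0, 1].
    """
    path = Path(path)
    if encoding not in ENCODINGS:
        raise ValueError(f"unknown encoding {encoding!r}; expected one of {ENCODINGS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if encoding == "array":
        values = np.load(path)
        if values.ndim != 2:
            raise ValueError(f"{path}: expected a 2-D array")
        if np.nanmin(values) < 0.0 or np.nanmax(values) > 1.0:
            raise ValueError(f"{path}: values outside [0, 1] (corrupt input)")
    else:
        raw = _read_raster(path)
        if raw.ndim != 2:
            raise ValueError(f"{path}: expected single-channel grayscale")
        maxval = _MAXVAL[encoding]
        if raw.min() < 0 or raw.max() > maxval:
            raise ValueError(f"{path}: intensities outside 0..{maxval} for {encoding}")
        values = raw.astype(float) / maxval
    return ProbabilityMap(values, pixel_size_um=pixel_size_um, sample_id=sample_id)


def write_probability_map(pmap: ProbabilityMap, path: str | Path, encoding: str) -> None:
    """Write a probability map; inverse of :func:`read_probability_map`."""
    path = Path(path)
    if encoding not in ENCODINGS:
        raise ValueError(f"unknown encoding {encoding!r}; expected one of {ENCODINGS}")
    if encoding == "array":
        np.save(path, pmap.values)
        return
    maxval = _MAXVAL[encoding]
    dtype = np.uint8 if encoding == "gray8" else np.uint16
    quantized = np.floor(pmap.values * maxval + 0.5).astype(dtype)
    _write_raster(path, quantized)


def read_mask(path: str | Path, role: str = "roi") -> BinaryMask:
    """Read a binary mask raster (any non-zero pixel is true)."""
    raw = _read_raster(Path(path))
    if raw.ndim != 2:
        raise ValueError(f"{path}: expected single-channel mask")
    return BinaryMask(raw != 0, role=role)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    _write_raster(Path(path), mask.values.astype(np.uint8) * 255)


def write_rgb(image: np.ndarray, path: str | Path) -> None:
    """Write an (H, W, 3) uint8 image."""
    _write_raster(Path(path), np.asarray(image, dtype=np.uint8))


def read_rgb(path: str | Path) -> np.ndarray:
    arr = _read_raster(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr[..., :3].astype(np.uint8)


# ---------------------------------------------------------------------------
# GeoJSON annotations


def read_annotations(path: str | Path) -> list[tuple[str, shapely.Geometry]]:
    """Read labeled polygons from a GeoJSON FeatureCollection.

    Each feature must carry a ``label`` property; geometries must be valid
    (self-intersecting polygons are rejected rather than silently fixed,
    since an invalid outline usually indicates a broken annotation export).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = json.loads(path.read_text())
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    out: list[tuple[str, shapely.Geometry]] = []
    for feat in data.get("features", []):
        props = feat.get("properties") or {}
        if "label" not in props:
            raise ValueError(f"{path}: feature missing 'label' property")
        geom = shapely_shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(f"{path}: invalid geometry for label {props['label']!r}")
        out.append((str(props["label"]), geom))
    return out


def rasterize(geom: shapely.Geometry, shape: tuple[int, int], role: str = "ground_truth") -> BinaryMask:
    """Rasterize a polygon with pixel-center containment.

    Pixel (row r, col c) is inside iff the point (x=c+0.5, y=r+0.5) lies
    strictly within the geometry.
    """
    h, w = shape
    cols, rows = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    inside = shapely.contains_xy(geom, cols.ravel(), rows.ravel()).reshape(h, w)
    return BinaryMask(inside, role=role)


# ---------------------------------------------------------------------------
# Detection tables

_DET_COLUMNS = ["x", "y", "width", "height", "score"]


def read_detections(
    path: str | Path,
    sample_id: str = "",
    frame: Optional[tuple[int, int]] = None,
) -> DetectionSet:
    """Read a detection CSV with columns x, y, width, height, score."""
    df = pd.read_csv(path)
    missing = [c for c in _DET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing detection columns {missing}")
    boxes = [
        Box(int(r.x), int(r.y), int(r.width), int(r.height), float(r.score))
        for r in df.itertuples()
    ]
    return DetectionSet(boxes, sample_id=sample_id, frame=frame)


def write_detections(dets: DetectionSet, path: str | Path) -> None:
    df = pd.DataFrame(
        [(b.x, b.y, b.width, b.height, b.score) for b in dets],
        columns=_DET_COLUMNS,
    )
    df.insert(0, "sample_id", dets.sample_id)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Manifests

MANIFEST_COLUMNS = ["sample_id", "wsi_id", "grade", "subtype", "tissue_mask", "gt_mask"]


def load_manifest(path: str | Path, base_dir: str | Path | None = None) -> list[SampleRecord]:
    """Load sample records from a manifest CSV.

    Columns: sample_id, wsi_id, grade, subtype, tissue_mask, gt_mask — the
    last two hold raster paths relative to ``base_dir`` (default: the
    manifest's directory); gt_mask may be empty for benign samples.
    Grades and subtypes are validated against the package enumerations and
    duplicate sample ids are rejected.
    """
    path = Path(path)
    base = Path(base_dir) if base_dir is not None else path.parent
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing manifest columns {missing}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate sample_id values {sorted(set(dupes))}")
    records = []
    for row in df.itertuples():
        tissue = (
            read_mask(base / row.tissue_mask, role="tissue")
            if getattr(row, "tissue_mask", "")
            else None
        )
        gt = (
            read_mask(base / row.gt_mask, role="ground_truth")
            if getattr(row, "gt_mask", "")
            else None
        )
        records.append(
            SampleRecord(
                sample_id=row.sample_id,
                wsi_id=row.wsi_id,
                grade=row.grade,
                subtype=row.subtype,
                tissue_mask=tissue,
                gt_mask=gt,
            )
        )
    return records


def write_manifest(records: list[SampleRecord], path: str | Path, mask_paths: dict[str, tuple[str, str]]) -> None:
    """Write a manifest CSV; ``mask_paths`` maps sample_id to relative
    (tissue_mask, gt_mask) paths ('' when absent)."""
    rows = []
    for rec in records:
        tissue, gt = mask_paths.get(rec.sample_id, ("", ""))
        rows.append((rec.sample_id, rec.wsi_id, rec.grade, rec.subtype, tissue, gt))
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def class_counts(records: list[SampleRecord]) -> pd.DataFrame:
    """Queryable per-(grade, subtype) sample counts for a cohort."""
    df = pd.DataFrame(
        [(r.grade, r.subtype) for r in records], columns=["grade", "subtype"]
    )
    return df.value_counts(["grade", "subtype"]).rename("n").reset_index()
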