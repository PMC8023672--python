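"""Reading and writing TIFF stacks, mask TIFFs, rendered PNGs and CSV cell tables.

Multi-channel stacks use the plane-per-channel multi-page TIFF dialect common
to IMC tooling; interleaved RGB TIFFs are rejected for stacks. Masks are
single-plane TIFFs read without rescaling so that object labels stay exact
integers. Cell tables are plain comma-separated UTF-8 CSV with a header.
"""

from __future__ import annotations

import glob as _glob
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import CellTable, ImageCollection, ImageStack, SegmentationMask, validate_collection

__all__ = [
    "LoadSpec",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "load_collection",
    "read_cell_table",
    "write_rendered",
    "export_cells",
]


@dataclass
class LoadSpec:
    """Where and how to load a collection of TIFFs.

    ``pattern`` is a glob resolved inside ``directory`` (or an absolute
    glob when ``directory`` is None). ``kind`` selects stack vs mask
    reading. ``on_read_scale`` optionally divides raw stack intensities,
    e.g. 65535 to map 16-bit data into [0, 1]; masks are never scaled.
    """

    directory: str | os.PathLike | None = None
    pattern: str = "*.tiff"
    kind: str = "stack"  # "stack" | "mask"
    channel_names: list[str] = field(default_factory=list)
    on_read_scale: float | None = None
    pixel_size_um: float | None = None


def _read_planes(path) -> tuple[np.ndarray, str]:
    """Return (planes, axes) where planes is (n_planes, rows, cols)."""
    with tifffile.TiffFile(os.fspath(path)) as tif:
        series = tif.series[0]
        axes = series.axes
        arr = series.asarray()
    if axes == "YX":
        return arr[np.newaxis, :, :], axes
    if axes == "YXS":
        raise ValueError(
            f"{path}: interleaved (samples-per-pixel) TIFF is not a valid "
            "plane-per-channel stack"
        )
    if arr.ndim == 2:
        return arr[np.newaxis, :, :], axes
    if arr.ndim == 3:
        return arr, axes
    raise ValueError(f"{path}: unsupported TIFF layout with axes {axes!r}")


def read_stack(
    path,
    channel_names: Sequence[str],
    on_read_scale: float | None = None,
    pixel_size_um: float | None = None,
) -> ImageStack:
    """Read a plane-per-channel TIFF as an :class:`ImageStack`.

    Planes are kept in stored page order and named by ``channel_names``.
    When ``on_read_scale`` is given, every intensity is divided by it
    (useful for 16-bit integer data). Negative or non-finite pixels are
    rejected.
    """
    planes, _ = _read_planes(path)
    if len(channel_names) != planes.shape[0]:
        raise ValueError(
            f"{path}: file has {planes.shape[0]} planes but {len(channel_names)} "
            "channel names were given"
        )
    pixels = np.moveaxis(planes, 0, -1).astype(float)
    if on_read_scale is not None:
        if on_read_scale <= 0:
            raise ValueError("on_read_scale must be positive")
        pixels = pixels / float(on_read_scale)
    if not np.all(np.isfinite(pixels)):
        raise ValueError(f"{path}: non-finite pixel values")
    if np.any(pixels < 0):
        raise ValueError(f"{path}: negative pixel values")
    return ImageStack(pixels, list(channel_names), pixel_size_um=pixel_size_um)


def write_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as a plane-per-channel TIFF (dtype preserved)."""
    planes = np.moveaxis(stack.pixels, -1, 0)
    # minisblack keeps 3-channel stacks page-per-plane instead of interleaved RGB
    tifffile.imwrite(os.fspath(path), planes, photometric="minisblack")


def read_mask(path, pixel_size_um: float | None = None) -> SegmentationMask:
    """Read a single-plane TIFF as a :class:`SegmentationMask`.

    Values are verified to be integer-valued and >= 0 and are never
    rescaled — scaling a label image corrupts object ids.
    """
    planes, _ = _read_planes(path)
    if planes.shape[0] != 1:
        raise ValueError(f"{path}: mask must be a single plane, found {planes.shape[0]}")
    try:
        return SegmentationMask(planes[0], pixel_size_um=pixel_size_um)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_mask(mask: SegmentationMask, path) -> None:
    """Write a mask as a single-plane TIFF of the smallest sufficient uint type."""
    labels = mask.labels
    top = int(labels.max(initial=0))
    dtype = np.uint16 if top <= np.iinfo(np.uint16).max else np.uint32
    tifffile.imwrite(os.fspath(path), labels.astype(dtype))


def _stem(path) -> str:
    # stem = basename up to the first dot, so 'E04_mask.ome.tiff' -> 'E04_mask'
    base = os.path.basename(os.fspath(path))
    return base.split(".", 1)[0]


def load_collection(spec: LoadSpec) -> ImageCollection:
    """Load every file matching the spec into one :class:`ImageCollection`.

    Image names are the filename stems (up to the first extension); name
    collisions are errors, never silently suffixed. Entries are sorted by
    name and the element metadata records filename provenance.
    """
    if spec.directory is not None:
        pattern = os.path.join(os.fspath(spec.directory), spec.pattern)
    else:
        pattern = spec.pattern
    paths = sorted(_glob.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no files match {pattern!r}")
    stems = [_stem(p) for p in paths]
    if len(set(stems)) != len(stems):
        dup = sorted({s for s in stems if stems.count(s) > 1})
        raise ValueError(f"duplicate image names from filename stems: {dup}")
    order = np.argsort(stems)
    entries = {}
    files = {}
    plane_counts = set()
    for i in order:
        path, name = paths[i], stems[i]
        if spec.kind == "mask":
            entries[name] = read_mask(path, pixel_size_um=spec.pixel_size_um)
        elif spec.kind == "stack":
            n_planes = _read_planes(path)[0].shape[0]
            plane_counts.add(n_planes)
            if len(plane_counts) > 1:
                raise ValueError(f"mixed plane counts across files: {sorted(plane_counts)}")
            entries[name] = read_stack(
                path,
                spec.channel_names,
                on_read_scale=spec.on_read_scale,
                pixel_size_um=spec.pixel_size_um,
            )
        else:
            raise ValueError(f"unknown kind {spec.kind!r} (expected 'stack' or 'mask')")
        files[name] = os.path.abspath(path)
    meta = pd.DataFrame({"source_file": [files[n] for n in entries]}, index=list(entries))
    collection = ImageCollection(entries, element_metadata=meta)
    report = validate_collection(collection)
    assert report.valid, report.violations
    return collection


def read_cell_table(
    path,
    marker_columns: Sequence[str],
    metadata_columns: Sequence[str] = (),
    image_column: str = "image_name",
    object_column: str = "object_id",
) -> CellTable:
    """Read a CSV cell table.

    Marker columns are parsed as finite reals; string metadata columns are
    stored as pandas categoricals. Duplicate ``(image_name, object_id)``
    keys and non-numeric expression values are errors.
    """
    df = pd.read_csv(path)
    declared = [image_column, object_column, *marker_columns, *metadata_columns]
    missing = [c for c in declared if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing declared columns {missing}")
    for col in marker_columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"{path}: non-numeric expression value in column {col!r} "
                f"at row {int(np.flatnonzero(bad)[0])}"
            )
        if vals.isna().any():
            raise ValueError(f"{path}: missing expression value in column {col!r}")
        df[col] = vals.astype(float)
    out = df[declared].rename(columns={image_column: "image_name", object_column: "object_id"})
    for col in metadata_columns:
        if out[col].dtype == object:
            out[col] = pd.Categorical(out[col].astype(str))
    return CellTable(out, list(marker_columns))


def write_rendered(img, path) -> None:
    """Write a rendered RGB image as lossless 8-bit PNG.

    Values must already lie in [0, 1]; out-of-range input is an error so
    that clipping is always an explicit caller decision. Quantization is
    ``round(v * 255)``, so a re-read differs by at most 1/255 per channel.
    """
    rgb = np.asarray(img.rgb, dtype=float)
    if np.any(rgb < 0) or np.any(rgb > 1) or not np.all(np.isfinite(rgb)):
        raise ValueError("rendered RGB values must lie in [0, 1]; clip explicitly first")
    quant = np.rint(rgb * 255.0).astype(np.uint8)
    iio.imwrite(os.fspath(path), quant, extension=".png")


def export_cells(table: CellTable, path) -> None:
    """Write a cell table as CSV, round-trippable by :func:`read_cell_table`.

    Expression values survive the round trip to 1e-9 relative (full ``repr``
    precision is written); keys and categorical metadata levels are
    preserved exactly. An empty table writes a header-only CSV.
    """
    cols = ["image_name", "object_id", *table.marker_names, *table.metadata_columns]
    out = table.data[cols]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
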