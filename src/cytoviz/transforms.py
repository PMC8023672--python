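"""Intensity normalization, channel scaling, per-cell measurement and
density-based image ranking.

Per-cell measurement extracts the mean intensity of every marker over each
object's pixels — the standard "mean ion counts per marker" read-out of IMC
pipelines. Density ranking reproduces the common selection step of ordering
images by the density of one or more cell types and taking the top image per
condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import CellTable, ImageCollection, ImageStack, SegmentationMask

__all__ = [
    "NormalizationSpec",
    "DensityRanking",
    "normalize",
    "scale_intensity",
    "measure_cells",
    "cell_density",
    "rank_images",
]


@dataclass
class NormalizationSpec:
    """How to map channel intensities into [0, 1].

    method
        ``minmax`` uses each channel's min/max; ``percentile`` uses the
        ``percentiles`` order statistics (linear interpolation, inclusive).
    percentiles
        ``[p_lo, p_hi]`` with 0 <= p_lo < p_hi <= 100; only used by the
        percentile method.
    scope_images
        ``separate`` computes bounds per image; ``joint`` pools the channel
        across all images of the collection.
    """

    method: str = "minmax"
    percentiles: tuple[float, float] = (0.0, 100.0)
    scope_images: str = "separate"

    def __post_init__(self):
        if self.method not in ("minmax", "percentile"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if self.scope_images not in ("separate", "joint"):
            raise ValueError(f"unknown image scope {self.scope_images!r}")
        p_lo, p_hi = self.percentiles
        if not (0 <= p_lo < p_hi <= 100):
            raise ValueError(f"percentiles must satisfy 0 <= lo < hi <= 100, got {self.percentiles}")


@dataclass
class DensityRanking:
    """Per-image cell-type densities with a deterministic ordering.

    ``table`` has one row per image: group, matching-cell count, image area
    (pixels, and mm^2 when the pixel size is known), density, rank within
    group and a ``selected`` flag on the top-density image of each group.
    Ties are broken by ascending image name.
    """

    table: pd.DataFrame
    types: list[str] = field(default_factory=list)
    type_column: str = "cell_type"

    @property
    def order(self) -> list[str]:
        return list(self.table["image_name"])

    def selected(self) -> dict[str, str]:
        """Group -> selected (highest-density) image name."""
        sel = self.table[self.table["selected"]]
        return dict(zip(sel["group"], sel["image_name"]))


def _bounds(values: np.ndarray, spec: NormalizationSpec) -> tuple[float, float]:
    if spec.method == "minmax":
        return float(values.min()), float(values.max())
    p_lo, p_hi = spec.percentiles
    lo, hi = np.percentile(values, [p_lo, p_hi], method="linear")
    return float(lo), float(hi)


def normalize(collection: ImageCollection, spec: NormalizationSpec | None = None) -> ImageCollection:
    """Map every channel of every stack into [0, 1].

    Values transform as ``clip((v - lo) / (hi - lo), 0, 1)`` with lo/hi the
    channel min/max (``minmax``) or percentiles, computed per image
    (``separate``) or pooled over the collection (``joint``). A degenerate
    channel (hi == lo) maps to all zeros.
    """
    if spec is None:
        spec = NormalizationSpec()
    names = collection.names
    if not names:
        raise ValueError("cannot normalize an empty collection")
    if collection.kind != "stack":
        raise ValueError(f"normalize expects a collection of stacks, got kind {collection.kind!r}")
    channels = collection[names[0]].channel_names

    joint_bounds: dict[str, tuple[float, float]] = {}
    if spec.scope_images == "joint":
        for ci, ch in enumerate(channels):
            pooled = np.concatenate(
                [collection[n].pixels[:, :, ci].ravel() for n in names]
            )
            joint_bounds[ch] = _bounds(pooled, spec)

    entries = {}
    for name in names:
        stack = collection[name]
        out = np.empty_like(stack.pixels, dtype=float)
        for ci, ch in enumerate(channels):
            plane = stack.pixels[:, :, ci]
            lo, hi = joint_bounds[ch] if spec.scope_images == "joint" else _bounds(plane, spec)
            if hi == lo:
                out[:, :, ci] = 0.0
            else:
                out[:, :, ci] = np.clip((plane - lo) / (hi - lo), 0.0, 1.0)
        entries[name] = ImageStack(out, channels, pixel_size_um=stack.pixel_size_um)
    return ImageCollection(entries, element_metadata=collection.element_metadata)


def scale_intensity(stack: ImageStack, factors: dict[str, float]) -> ImageStack:
    """Multiply named channels elementwise by positive factors.

    Unnamed channels pass through unchanged. No clipping happens here —
    clipping is a rendering-time decision. Composes multiplicatively:
    scaling by ``a`` then ``b`` equals scaling by ``a*b``.
    """
    unknown = [ch for ch in factors if ch not in stack.channel_names]
    if unknown:
        raise KeyError(f"unknown channels: {unknown}")
    bad = {ch: f for ch, f in factors.items() if not f > 0}
    if bad:
        raise ValueError(f"scale factors must be positive: {bad}")
    pixels = stack.pixels.copy()
    for ch, f in factors.items():
        ci = stack.channel_names.index(ch)
        pixels[:, :, ci] = pixels[:, :, ci] * float(f)
    return ImageStack(pixels, stack.channel_names, pixel_size_um=stack.pixel_size_um)


def measure_cells(stack: ImageStack, mask: SegmentationMask, image_name: str = "image") -> CellTable:
    """Mean marker intensity per object, plus area and centroid.

    One row per positive label in the mask. ``expression[cell, ch]`` is the
    arithmetic mean of channel ``ch`` over the cell's pixels. Metadata
    columns: ``area_px`` (pixel count), ``centroid_row``/``centroid_col``
    (mean member-pixel coordinates, 0-based).
    """
    if stack.shape != mask.shape:
        raise ValueError(f"dimension mismatch: stack {stack.shape} vs mask {mask.shape}")
    ids = mask.object_ids
    if ids.size == 0:
        empty = pd.DataFrame(
            {
                "image_name": pd.Series([], dtype=str),
                "object_id": pd.Series([], dtype=np.int64),
                **{ch: pd.Series([], dtype=float) for ch in stack.channel_names},
                "area_px": pd.Series([], dtype=np.int64),
                "centroid_row": pd.Series([], dtype=float),
                "centroid_col": pd.Series([], dtype=float),
            }
        )
        return CellTable(empty, stack.channel_names)

    labels = mask.labels
    means = {
        ch: ndimage.mean(stack.pixels[:, :, ci], labels=labels, index=ids)
        for ci, ch in enumerate(stack.channel_names)
    }
    areas = ndimage.sum_labels(np.ones_like(labels), labels=labels, index=ids).astype(np.int64)
    centroids = np.array(ndimage.center_of_mass(np.ones_like(labels), labels=labels, index=ids))
    df = pd.DataFrame(
        {
            "image_name": image_name,
            "object_id": ids.astype(np.int64),
            **means,
            "area_px": areas,
            "centroid_row": centroids[:, 0],
            "centroid_col": centroids[:, 1],
        }
    )
    return CellTable(df, stack.channel_names)


def cell_density(
    cells: CellTable,
    image_name: str,
    mask: SegmentationMask,
    types,
    type_column: str,
) -> float:
    """Density of cells of the given types on one image.

    The denominator is the full image area: per megapixel, or per mm^2 when
    the mask carries a pixel size. (No tissue segmentation is applied.)
    """
    if type_column not in cells.data.columns:
        raise KeyError(f"unknown type column {type_column!r}")
    types = set(types)
    sub = cells.data[cells.data["image_name"] == image_name]
    count = int(sub[type_column].isin(types).sum())
    if mask.pixel_size_um is not None:
        return count / mask.area_mm2
    return count / mask.area_px * 1e6


def rank_images(
    cells: CellTable,
    masks: ImageCollection,
    types,
    type_column: str,
    group_column: str | None = None,
) -> DensityRanking:
    """Rank images by cell-type density, optionally within metadata groups.

    Within each group (a value of ``group_column`` in the masks' element
    metadata, or one global group) images are sorted by descending density
    with ties broken by ascending image name; the top image per group is
    flagged ``selected``. Images with a missing group value are placed in
    group ``"NA"``.
    """
    if type_column not in cells.data.columns:
        raise KeyError(f"unknown type column {type_column!r}")
    cell_images = set(cells.data["image_name"].unique())
    missing_masks = sorted(cell_images - set(masks.names))
    if missing_masks:
        raise ValueError(f"images in the cell table without a mask: {missing_masks}")

    rows = []
    for name in masks.names:
        mask = masks[name]
        if group_column is None:
            group = "all"
        else:
            group = None
            if group_column in masks.element_metadata.columns:
                val = masks.element_metadata.loc[name, group_column]
                group = None if pd.isna(val) else str(val)
            if group is None:
                group = "NA"
        rows.append(
            {
                "image_name": name,
                "group": group,
                "count": int(
                    (
                        (cells.data["image_name"] == name)
                        & cells.data[type_column].isin(set(types))
                    ).sum()
                ),
                "area_px": mask.area_px,
                "area_mm2": mask.area_mm2,
                "density": cell_density(cells, name, mask, types, type_column),
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["group", "density", "image_name"], ascending=[True, False, True]
    ).reset_index(drop=True)
    df["rank"] = df.groupby("group").cumcount() + 1
    df["selected"] = df["rank"] == 1
    return DensityRanking(table=df, types=sorted(str(t) for t in types), type_column=type_column)
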