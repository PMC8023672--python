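"""Core in-memory containers for multiplexed imaging data.

The data model mirrors the standard objects of highly multiplexed imaging
(e.g. imaging mass cytometry) analysis:

* :class:`ImageStack` — a multi-channel intensity image, one channel per
  marker.
* :class:`SegmentationMask` — an integer-labelled image; 0 is background,
  each positive label is one cell object.
* :class:`ImageCollection` — an ordered, uniquely named set of stacks or
  masks with per-image metadata (condition, donor, ...).
* :class:`CellTable` — the per-cell data matrix keyed by
  ``(image_name, object_id)``: marker expressions plus metadata columns.

Coordinate convention throughout the package: ``(row, col)``, 0-based,
origin at the top-left, matching raster file order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImageStack",
    "SegmentationMask",
    "ImageCollection",
    "CellTable",
    "ChannelDisplay",
    "ColorSpec",
    "PairedSet",
    "ValidationReport",
    "pair_by_name",
    "validate_collection",
]

MAX_COMPOSITE_CHANNELS = 6


def _check_pixel_size(pixel_size_um):
    if pixel_size_um is not None:
        pixel_size_um = float(pixel_size_um)
        if not np.isfinite(pixel_size_um) or pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be a positive finite real")
    return pixel_size_um


class ImageStack:
    """A rows x cols x channels array of non-negative marker intensities.

    Parameters
    ----------
    pixels
        3-D float array ``(rows, cols, channels)``. A 2-D array is accepted
        and treated as a single channel. All values must be finite and >= 0.
    channel_names
        Ordered unique non-empty channel (marker) names, one per channel.
    pixel_size_um
        Optional physical edge length of one pixel in micrometres.
    """

    def __init__(self, pixels, channel_names: Sequence[str], pixel_size_um=None):
        pixels = np.asarray(pixels, dtype=float)
        if pixels.ndim == 2:
            pixels = pixels[:, :, np.newaxis]
        if pixels.ndim != 3:
            raise ValueError(f"pixels must be 2-D or 3-D, got ndim={pixels.ndim}")
        names = [str(n) for n in channel_names]
        if len(names) != pixels.shape[2]:
            raise ValueError(
                f"channel_names has {len(names)} entries but pixels has "
                f"{pixels.shape[2]} channels"
            )
        if any(n == "" for n in names):
            raise ValueError("channel names must be non-empty")
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(pixels)):
            raise ValueError("pixel intensities must be finite")
        if np.any(pixels < 0):
            raise ValueError("pixel intensities must be >= 0")
        self.pixels = pixels
        self.channel_names = names
        self.pixel_size_um = _check_pixel_size(pixel_size_um)

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) spatial dimensions."""
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """Return the 2-D plane of one named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.channel_names}")
        return self.pixels[:, :, idx]

    def __repr__(self) -> str:
        r, c = self.shape
        return f"ImageStack({r}x{c}, channels={self.channel_names})"


class SegmentationMask:
    """A rows x cols image of non-negative integer object labels.

    Label 0 is background; positive labels identify cell objects. Object ids
    need not be consecutive.
    """

    def __init__(self, labels, pixel_size_um=None):
        arr = np.asarray(labels)
        if arr.ndim != 2:
            raise ValueError(f"mask labels must be 2-D, got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer):
            flt = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(flt)):
                raise ValueError("mask labels must be finite")
            rounded = np.rint(flt)
            if np.any(flt != rounded):
                bad = np.argwhere(flt != rounded)[0]
                raise ValueError(
                    f"mask value {flt[tuple(bad)]} at (row={bad[0]}, col={bad[1]}) "
                    "is not an exact integer"
                )
            arr = rounded.astype(np.int64)
        if np.any(arr < 0):
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(f"negative label at (row={bad[0]}, col={bad[1]})")
        self.labels = arr.astype(np.int64, copy=False)
        self.pixel_size_um = _check_pixel_size(pixel_size_um)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def object_ids(self) -> np.ndarray:
        """Sorted array of positive labels present in the mask."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def area_px(self) -> int:
        return int(self.labels.size)

    @property
    def area_mm2(self) -> float | None:
        """Image area in mm^2, or None when the pixel size is unknown."""
        if self.pixel_size_um is None:
            return None
        return self.labels.size * (self.pixel_size_um / 1000.0) ** 2

    def __repr__(self) -> str:
        r, c = self.shape
        return f"SegmentationMask({r}x{c}, n_objects={len(self.object_ids)})"


class ImageCollection:
    """Ordered, uniquely named set of stacks or masks with per-image metadata.

    All entries in one collection must be of the same kind (all stacks or all
    masks); stacks must share identical channel names in identical order.
    These invariants are checked on construction; :func:`validate_collection`
    re-checks them non-destructively for collections assembled elsewhere.
    """

    def __init__(
        self,
        entries: Mapping[str, ImageStack | SegmentationMask],
        element_metadata: pd.DataFrame | None = None,
        validate: bool = True,
    ):
        self._entries: dict[str, ImageStack | SegmentationMask] = dict(entries)
        if element_metadata is None:
            element_metadata = pd.DataFrame(index=pd.Index(list(self._entries), name="image_name"))
        else:
            element_metadata = element_metadata.copy()
            element_metadata.index.name = "image_name"
        self.element_metadata = element_metadata
        if validate:
            report = validate_collection(self)
            if report.violations:
                raise ValueError("invalid ImageCollection: " + "; ".join(report.violations))

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    @property
    def kind(self) -> str:
        """'stack', 'mask', 'empty' or 'mixed'."""
        kinds = {
            "stack" if isinstance(v, ImageStack) else "mask" for v in self._entries.values()
        }
        if not kinds:
            return "empty"
        if len(kinds) > 1:
            return "mixed"
        return kinds.pop()

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __getitem__(self, name: str) -> ImageStack | SegmentationMask:
        return self._entries[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def items(self):
        return self._entries.items()

    def __repr__(self) -> str:
        return f"ImageCollection(kind={self.kind!r}, n={len(self)})"


class CellTable:
    """Per-cell expression matrix plus metadata, keyed by (image_name, object_id).

    Parameters
    ----------
    data
        DataFrame with columns ``image_name`` (str), ``object_id`` (positive
        int), one numeric column per marker, and any further metadata columns.
    marker_names
        Ordered marker column names; all must be present and numeric/finite.
    """

    KEY_COLUMNS = ("image_name", "object_id")

    def __init__(self, data: pd.DataFrame, marker_names: Sequence[str]):
        data = data.copy()
        marker_names = [str(m) for m in marker_names]
        for col in self.KEY_COLUMNS:
            if col not in data.columns:
                raise ValueError(f"missing key column {col!r}")
        if len(set(marker_names)) != len(marker_names):
            raise ValueError("marker names must be unique")
        missing = [m for m in marker_names if m not in data.columns]
        if missing:
            raise ValueError(f"marker columns missing from table: {missing}")
        data["image_name"] = data["image_name"].astype(str)
        data["object_id"] = data["object_id"].astype(np.int64)
        if len(data) and np.any(data["object_id"].to_numpy() <= 0):
            raise ValueError("object_id values must be positive integers")
        dup = data.duplicated(subset=list(self.KEY_COLUMNS))
        if dup.any():
            offenders = data.loc[dup, list(self.KEY_COLUMNS)].to_records(index=False).tolist()
            raise ValueError(f"duplicate (image_name, object_id) keys: {offenders[:5]}")
        expr = data[marker_names].to_numpy(dtype=float) if len(data) else np.empty((0, len(marker_names)))
        if expr.size and not np.all(np.isfinite(expr)):
            raise ValueError("expression values must be finite reals")
        data[marker_names] = expr
        self.data = data.reset_index(drop=True)
        self.marker_names = marker_names

    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def expression(self) -> np.ndarray:
        """Cells x markers matrix as a float array."""
        return self.data[self.marker_names].to_numpy(dtype=float)

    @property
    def metadata_columns(self) -> list[str]:
        keys = set(self.KEY_COLUMNS) | set(self.marker_names)
        return [c for c in self.data.columns if c not in keys]

    def for_image(self, image_name: str) -> "CellTable":
        """Subset of rows belonging to one image, row order preserved."""
        sub = self.data[self.data["image_name"] == image_name]
        return CellTable(sub, self.marker_names)

    def subset(self, row_mask) -> "CellTable":
        return CellTable(self.data[np.asarray(row_mask, dtype=bool)], self.marker_names)

    def __repr__(self) -> str:
        return f"CellTable(n_cells={self.n_cells}, markers={self.marker_names})"


@dataclass
class ChannelDisplay:
    """Display parameters for one channel of a composite.

    ``contrast``/``background``/``gamma`` implement the usual b/c/g
    adjustment; ``range_`` maps the adjusted value linearly into [0, 1]
    (default: the adjusted channel's own min/max).
    """

    color: tuple[float, float, float]
    range_: tuple[float, float] | None = None
    contrast: float = 1.0
    background: float = 0.0
    gamma: float = 1.0

    def __post_init__(self):
        self.color = tuple(float(c) for c in self.color)
        if len(self.color) != 3 or any(not (0.0 <= c <= 1.0) for c in self.color):
            raise ValueError(f"color must be an RGB triple in [0,1]^3, got {self.color}")
        if self.range_ is not None:
            lo, hi = (float(self.range_[0]), float(self.range_[1]))
            if not lo < hi:
                raise ValueError(f"range must satisfy lo < hi, got {(lo, hi)}")
            self.range_ = (lo, hi)
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


class ColorSpec:
    """Per-channel display assignments for a composite (at most six channels)."""

    def __init__(self, channels: Mapping[str, ChannelDisplay]):
        self.channels = dict(channels)
        if len(self.channels) > MAX_COMPOSITE_CHANNELS:
            raise ValueError(
                f"composites support at most {MAX_COMPOSITE_CHANNELS} channels; "
                f"{len(self.channels)} requested"
            )

    def validate_against(self, stack: ImageStack) -> None:
        unknown = [ch for ch in self.channels if ch not in stack.channel_names]
        if unknown:
            raise KeyError(f"channels not present in stack: {unknown}")

    def __len__(self) -> int:
        return len(self.channels)


@dataclass
class PairedSet:
    """Result of pairing images, masks and cell rows by image name."""

    pairs: dict[str, dict]  # name -> {"stack": ..., "mask": ..., "cells": CellTable}
    images_only: list[str] = field(default_factory=list)
    masks_only: list[str] = field(default_factory=list)
    orphan_object_ids: dict[str, list[int]] = field(default_factory=dict)


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations


def validate_collection(c: ImageCollection) -> ValidationReport:
    """Check :class:`ImageCollection` invariants and report violations.

    Returns an empty report iff the collection is valid. Checks: unique
    names (guaranteed by the dict representation but re-checked on the
    metadata index), metadata/entry correspondence, single kind, and
    identical ordered channel names across stacks.
    """
    violations: list[str] = []
    names = c.names
    meta_index = list(c.element_metadata.index)
    if sorted(meta_index) != sorted(names):
        violations.append(
            f"element_metadata rows do not correspond 1:1 to entries "
            f"(entries={len(names)}, metadata rows={len(meta_index)})"
        )
    if len(set(meta_index)) != len(meta_index):
        violations.append("duplicate image names in element_metadata")
    kinds = {name: ("stack" if isinstance(c[name], ImageStack) else "mask") for name in names}
    if len(set(kinds.values())) > 1:
        violations.append(f"mixed kinds in one collection: {sorted(set(kinds.values()))}")
    stacks = [name for name in names if kinds[name] == "stack"]
    if stacks:
        ref = c[stacks[0]].channel_names
        for name in stacks[1:]:
            if c[name].channel_names != ref:
                violations.append(
                    f"channel names of {name!r} ({c[name].channel_names}) differ "
                    f"from {stacks[0]!r} ({ref})"
                )
    return ValidationReport(violations)


def pair_by_name(
    images: ImageCollection | None,
    masks: ImageCollection | None,
    cells: CellTable | None = None,
) -> PairedSet:
    """Pair stacks, masks and cell rows by exact image-name equality.

    Pairing is by exact string match — no fuzzy matching — because a silent
    stack/mask mismatch is the principal QC hazard in this workflow.

    Returns per image name the stack (may be absent), the mask (may be
    absent) and the cell rows for that image; names present in only one
    collection are reported as ``images_only`` / ``masks_only``. Cell object
    ids absent from the paired mask are tolerated but surfaced in
    ``orphan_object_ids``; rendering decides their fate.

    Raises
    ------
    ValueError
        If a same-named stack and mask differ in pixel dimensions, or a cell
        row references an image name present in neither collection.
    """
    image_names = list(images.names) if images is not None else []
    mask_names = list(masks.names) if masks is not None else []
    common = [n for n in image_names if n in mask_names]
    for name in common:
        if images[name].shape != masks[name].shape:
            raise ValueError(
                f"dimension mismatch for image {name!r}: stack {images[name].shape} "
                f"vs mask {masks[name].shape}"
            )
    known = set(image_names) | set(mask_names)
    if cells is not None and cells.n_cells:
        referenced = set(cells.data["image_name"].unique())
        missing = sorted(referenced - known)
        if missing:
            raise ValueError(f"cell rows reference unknown image names: {missing}")

    all_names = list(dict.fromkeys(image_names + mask_names))
    pairs: dict[str, dict] = {}
    orphans: dict[str, list[int]] = {}
    for name in all_names:
        stack = images[name] if (images is not None and name in images) else None
        mask = masks[name] if (masks is not None and name in masks) else None
        sub = cells.for_image(name) if cells is not None else None
        if mask is not None and sub is not None and sub.n_cells:
            present = set(int(i) for i in mask.object_ids)
            ids = [int(i) for i in sub.data["object_id"] if int(i) not in present]
            if ids:
                orphans[name] = ids
        pairs[name] = {"stack": stack, "mask": mask, "cells": sub}
    return PairedSet(
        pairs=pairs,
        images_only=[n for n in image_names if n not in mask_names],
        masks_only=[n for n in mask_names if n not in image_names],
        orphan_object_ids=orphans,
    )
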