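"""Rendering engine: mask colouring, multi-channel composites, outlines,
scale bars and image grids.

Two complementary views of multiplexed data are produced here. Cell-level
views colour segmentation masks by a per-cell feature (marker expression or
numeric metadata, via a colour ramp) or by a categorical metadata column
(via a palette). Pixel-level views blend up to six intensity channels into
an RGB composite, each channel contributing its b/c/g-adjusted, range-mapped
intensity times an assigned colour; contributions add and clip at 1, which
reproduces the familiar additive look of marker overlays (yellow + blue
mixing, etc.).

All colour interpolation is linear in RGB space, pinned for determinism.
Background defaults to black and unselected/missing cells to white, the
conventions used for mask-based cell-type figures in this field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    MAX_COMPOSITE_CHANNELS,
    CellTable,
    ChannelDisplay,
    ColorSpec,
    ImageStack,
    SegmentationMask,
)

__all__ = [
    "RenderedImage",
    "CategoricalPalette",
    "hex_to_rgb",
    "colorize_mask_by_feature",
    "colorize_mask_by_metadata",
    "composite_pixels",
    "outline_cells",
    "add_scale_bar",
    "render_grid",
    "boundary_pixels",
]

BLACK = (0.0, 0.0, 0.0)
WHITE = (1.0, 1.0, 1.0)


def hex_to_rgb(color: str | Sequence[float]) -> tuple[float, float, float]:
    """Convert '#RRGGBB' (or an RGB triple) to a float triple in [0,1]."""
    if isinstance(color, str):
        s = color.lstrip("#")
        if len(s) != 6:
            raise ValueError(f"expected '#RRGGBB' hex colour, got {color!r}")
        return tuple(int(s[i : i + 2], 16) / 255.0 for i in (0, 2, 4))
    rgb = tuple(float(c) for c in color)
    if len(rgb) != 3 or any(not (0 <= c <= 1) for c in rgb):
        raise ValueError(f"RGB triple must lie in [0,1]^3, got {color!r}")
    return rgb


@dataclass
class RenderedImage:
    """An RGB image in [0,1] plus structured annotations.

    Annotations are ``(kind, payload)`` pairs with kind in
    ``{"scale_bar", "title", "legend_entry", "warning"}``; drawing of
    legends is deliberately minimal — the structured record is the API.
    """

    rgb: np.ndarray
    annotations: list[tuple[str, dict]] = field(default_factory=list)
    pixel_size_um: float | None = None

    def __post_init__(self):
        rgb = np.asarray(self.rgb, dtype=float)
        if rgb.ndim != 3 or rgb.shape[2] != 3:
            raise ValueError(f"rgb must be rows x cols x 3, got shape {rgb.shape}")
        if np.any(rgb < 0) or np.any(rgb > 1) or not np.all(np.isfinite(rgb)):
            raise ValueError("rgb values must lie in [0, 1]")
        self.rgb = rgb

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    def annotate(self, kind: str, **payload) -> "RenderedImage":
        self.annotations.append((kind, payload))
        return self


@dataclass
class CategoricalPalette:
    """Level -> RGB mapping with missing/background defaults.

    ``missing_color`` (default white) paints objects that are absent from
    the cell table or outside the plotted subset; ``background_color``
    (default black) paints label 0.
    """

    colors: dict[str, tuple[float, float, float]]
    missing_color: tuple[float, float, float] = WHITE
    background_color: tuple[float, float, float] = BLACK

    def __post_init__(self):
        self.colors = {str(k): hex_to_rgb(v) for k, v in self.colors.items()}
        self.missing_color = hex_to_rgb(self.missing_color)
        self.background_color = hex_to_rgb(self.background_color)

    def __getitem__(self, level: str) -> tuple[float, float, float]:
        return self.colors[str(level)]

    def __contains__(self, level) -> bool:
        return str(level) in self.colors


def _interp_ramp(t: np.ndarray, ramp: list[tuple[float, float, float]]) -> np.ndarray:
    """Piecewise-linear interpolation along a colour ramp, linear in RGB."""
    ramp_arr = np.asarray(ramp, dtype=float)  # (k, 3)
    k = ramp_arr.shape[0]
    positions = np.linspace(0.0, 1.0, k)
    out = np.empty((t.shape[0], 3))
    for c in range(3):
        out[:, c] = np.interp(t, positions, ramp_arr[:, c])
    return out


def _paint_objects(
    mask: SegmentationMask,
    colors_by_id: dict[int, tuple[float, float, float]],
    missing_color,
    background_color,
) -> np.ndarray:
    """Fill each object's pixels with its colour via a label lookup table."""
    labels = mask.labels
    top = int(labels.max(initial=0))
    lut = np.empty((top + 1, 3), dtype=float)
    lut[:] = missing_color
    lut[0] = background_color
    for oid, rgb in colors_by_id.items():
        if 0 < oid <= top:
            lut[oid] = rgb
    return lut[labels]


def colorize_mask_by_feature(
    mask: SegmentationMask,
    cells: CellTable,
    image_name: str,
    feature: str,
    ramp: Sequence = (BLACK, (1.0, 0.0, 0.0)),
    range_: tuple[float, float] | None = None,
    missing_color=WHITE,
    background_color=BLACK,
) -> RenderedImage:
    """Colour mask objects by a continuous per-cell feature.

    Each cell's feature value ``v`` is mapped to a ramp position
    ``t = clip((v - lo) / (hi - lo), 0, 1)`` and interpolated
    piecewise-linearly (in RGB) along the ramp. ``[lo, hi]`` defaults to the
    feature's min/max over the plotted cells of this image; pass an explicit
    range for cross-image comparability. A degenerate range (one cell, or
    all values equal) maps everything to the first ramp colour. Objects in
    the mask but absent from the table get ``missing_color``; object ids in
    the table but not in the mask produce a warning annotation, not an error.
    """
    if len(ramp) < 2:
        raise ValueError("ramp needs at least two colours")
    ramp_rgb = [hex_to_rgb(c) for c in ramp]
    sub = cells.for_image(image_name)
    if feature not in sub.data.columns:
        raise KeyError(f"unknown feature {feature!r}")
    values = sub.data[feature].to_numpy(dtype=float)
    if values.size and np.all(np.isnan(values)):
        raise ValueError(f"feature {feature!r} is all-NaN for image {image_name!r}")

    if range_ is not None:
        lo, hi = float(range_[0]), float(range_[1])
        if not lo < hi:
            raise ValueError(f"range must satisfy lo < hi, got {range_}")
    elif values.size:
        lo, hi = float(np.nanmin(values)), float(np.nanmax(values))
    else:
        lo, hi = 0.0, 1.0

    if hi > lo:
        t = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
    else:
        t = np.zeros_like(values)
    cell_colors = _interp_ramp(t, ramp_rgb)
    ids = sub.data["object_id"].to_numpy()
    colors_by_id = {int(i): tuple(c) for i, c in zip(ids, cell_colors)}

    rgb = _paint_objects(mask, colors_by_id, hex_to_rgb(missing_color), hex_to_rgb(background_color))
    img = RenderedImage(rgb, pixel_size_um=mask.pixel_size_um)
    img.annotate("legend_entry", feature=feature, range=(lo, hi), ramp=ramp_rgb)
    present = set(int(i) for i in mask.object_ids)
    orphans = sorted(int(i) for i in ids if int(i) not in present)
    if orphans:
        img.annotate("warning", message="object ids in table but not in mask", object_ids=orphans)
    return img


def colorize_mask_by_metadata(
    mask: SegmentationMask,
    cells: CellTable,
    image_name: str,
    column: str,
    palette: CategoricalPalette,
    subset: set | None = None,
) -> RenderedImage:
    """Colour mask objects by a categorical metadata column.

    Cells whose level is in ``subset`` (all levels when None) are painted by
    the palette; all other cells — outside the subset or missing from the
    table — get the palette's missing colour, so selected populations stand
    out against white "other" cells on a black background. A missing palette
    entry for a plotted level is an error naming the level.
    """
    sub = cells.for_image(image_name)
    if column not in sub.data.columns:
        raise KeyError(f"unknown metadata column {column!r}")
    levels = sub.data[column].astype(str).to_numpy()
    plotted = sorted(set(levels) if subset is None else {str(s) for s in subset})
    for level in plotted:
        if level in set(levels) and level not in palette:
            raise KeyError(f"palette has no colour for level {level!r}")

    ids = sub.data["object_id"].to_numpy()
    colors_by_id = {}
    for oid, level in zip(ids, levels):
        if level in plotted and level in palette:
            colors_by_id[int(oid)] = palette[level]
    rgb = _paint_objects(mask, colors_by_id, palette.missing_color, palette.background_color)
    img = RenderedImage(rgb, pixel_size_um=mask.pixel_size_um)
    for level in plotted:
        if level in palette:
            img.annotate("legend_entry", column=column, level=level, color=palette[level])
    present = set(int(i) for i in mask.object_ids)
    orphans = sorted(int(i) for i in ids if int(i) not in present)
    if orphans:
        img.annotate("warning", message="object ids in table but not in mask", object_ids=orphans)
    missing_from_table = sorted(present - set(int(i) for i in ids))
    if missing_from_table:
        img.annotate(
            "warning", message="mask objects absent from table", object_ids=missing_from_table
        )
    return img


def _bcg_map(plane: np.ndarray, disp: ChannelDisplay) -> np.ndarray:
    """b/c/g adjust then range-map one channel into [0,1].

    Pinned order of operations: multiply by contrast, add background, clip
    at 0 (gamma of a negative base is undefined), apply gamma, then map
    ``[lo, hi]`` linearly onto [0, 1] with clipping.
    """
    u = plane * disp.contrast + disp.background
    u = np.clip(u, 0.0, None)
    if disp.gamma != 1.0:
        u = u ** disp.gamma
    if disp.range_ is not None:
        lo, hi = disp.range_
    else:
        lo, hi = float(u.min()), float(u.max())
        if hi == lo:
            return np.zeros_like(u)
    return np.clip((u - lo) / (hi - lo), 0.0, 1.0)


def composite_pixels(stack: ImageStack, spec: ColorSpec) -> RenderedImage:
    """Blend up to six channels into an RGB composite.

    Each requested channel contributes its mapped intensity times its
    colour; contributions are summed and clipped at 1 (additive blending).
    Channels not in the spec are ignored. More than six channels is a hard
    error — beyond six, colour collisions make composites misleading.
    """
    if len(spec) == 0:
        raise ValueError("composite requires at least one channel")
    if len(spec) > MAX_COMPOSITE_CHANNELS:
        raise ValueError(
            f"composites support at most {MAX_COMPOSITE_CHANNELS} channels; "
            f"{len(spec)} requested"
        )
    spec.validate_against(stack)
    rows, cols = stack.shape
    acc = np.zeros((rows, cols, 3), dtype=float)
    img = RenderedImage(acc, pixel_size_um=stack.pixel_size_um)
    # accumulate in sorted channel order: float addition is not bit-exactly
    # commutative, and the blend must be invariant to the spec's dict order
    for ch in sorted(spec.channels):
        disp = spec.channels[ch]
        u = _bcg_map(stack.channel(ch), disp)
        acc = acc + u[:, :, np.newaxis] * np.asarray(disp.color)
        img.annotate("legend_entry", channel=ch, color=disp.color)
    img.rgb = np.clip(acc, 0.0, 1.0)
    return img


def boundary_pixels(labels: np.ndarray) -> np.ndarray:
    """Boolean map of object pixels with an 8-adjacent different label.

    A pixel belongs to the boundary of its object iff it is positive and at
    least one of its 8 in-image neighbours carries a different label
    (another object or background). Pixels on the image border are not
    boundary unless an in-image neighbour differs.
    """
    lab = np.asarray(labels).astype(np.int64, copy=False)  # -1 sentinel needs signed ints
    diff = np.zeros(lab.shape, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.full_like(lab, -1)
            rs = slice(max(dr, 0), lab.shape[0] + min(dr, 0))
            rd = slice(max(-dr, 0), lab.shape[0] + min(-dr, 0))
            cs = slice(max(dc, 0), lab.shape[1] + min(dc, 0))
            cd = slice(max(-dc, 0), lab.shape[1] + min(-dc, 0))
            shifted[rd, cd] = lab[rs, cs]
            valid = shifted != -1
            diff |= valid & (shifted != lab)
    return diff & (lab > 0)


def outline_cells(
    base: RenderedImage,
    mask: SegmentationMask,
    cells: CellTable | None = None,
    column: str | None = None,
    palette: CategoricalPalette | None = None,
    thickness: int = 1,
    image_name: str | None = None,
    default_color=WHITE,
    restrict_to: set | None = None,
) -> RenderedImage:
    """Draw cell outlines onto a rendered image (segmentation QC overlay).

    Boundary pixels (8-connectivity) of each object are overwritten with the
    object's outline colour: the palette colour of its ``column`` level when
    given, else ``default_color``. Thickness grows by iterative inward
    dilation, so outlines never spill outside their object. Interior pixels
    are untouched. ``restrict_to`` limits outlining to a set of object ids
    (used for visualizing gated selections).
    """
    if thickness < 1:
        raise ValueError("thickness must be >= 1")
    if base.shape != mask.shape:
        raise ValueError(f"dimension mismatch: base {base.shape} vs mask {mask.shape}")

    color_by_id: dict[int, tuple[float, float, float]] = {}
    if column is not None:
        if cells is None or palette is None:
            raise ValueError("colouring outlines by metadata requires cells and palette")
        sub = cells if image_name is None else cells.for_image(image_name)
        if column not in sub.data.columns:
            raise KeyError(f"unknown metadata column {column!r}")
        for oid, level in zip(sub.data["object_id"], sub.data[column].astype(str)):
            if level in palette:
                color_by_id[int(oid)] = palette[level]
            else:
                raise KeyError(f"palette has no colour for level {level!r}")
    default_rgb = hex_to_rgb(default_color)

    rgb = base.rgb.copy()
    remaining = mask.labels.copy()
    if restrict_to is not None:
        keep = np.isin(remaining, list(restrict_to) or [0])
        remaining = np.where(keep, remaining, 0)
    for _ in range(thickness):
        ring = boundary_pixels(remaining)
        if not ring.any():
            break
        ring_labels = remaining[ring]
        colors = np.array(
            [color_by_id.get(int(l), default_rgb) for l in ring_labels], dtype=float
        )
        rgb[ring] = colors
        remaining[ring] = 0  # peel the ring so the next pass finds the inner ring
    out = RenderedImage(rgb, annotations=list(base.annotations), pixel_size_um=base.pixel_size_um)
    out.annotate("legend_entry", outline=column or "segmentation", thickness=thickness)
    return out


def add_scale_bar(
    img: RenderedImage,
    length_um: float,
    color=WHITE,
    pixel_size_um: float | None = None,
) -> RenderedImage:
    """Draw a horizontal scale bar in the bottom-left margin.

    The bar spans ``round(length_um / pixel_size_um)`` pixels. The pixel
    size comes from the rendered image (inherited from its source) unless
    overridden. A bar longer than the image is an error.
    """
    px = pixel_size_um if pixel_size_um is not None else img.pixel_size_um
    if px is None:
        raise ValueError("pixel size unknown; cannot draw a physical scale bar")
    if length_um <= 0:
        raise ValueError("scale bar length must be positive")
    bar_px = int(round(length_um / px))
    rows, cols = img.shape
    if bar_px > cols:
        raise ValueError(
            f"scale bar of {bar_px} px exceeds image width {cols} px"
        )
    margin = max(2, rows // 20)
    bar_h = max(1, rows // 100)
    r1 = rows - margin
    r0 = max(0, r1 - bar_h)
    c0 = min(margin, cols - bar_px)
    rgb = img.rgb.copy()
    rgb[r0:r1, c0 : c0 + bar_px] = hex_to_rgb(color)
    out = RenderedImage(rgb, annotations=list(img.annotations), pixel_size_um=img.pixel_size_um)
    out.annotate("scale_bar", length_um=float(length_um), length_px=bar_px)
    return out


def render_grid(
    items: Sequence[RenderedImage],
    columns: int,
    margin_px: int = 2,
    background=BLACK,
) -> RenderedImage:
    """Tile rendered panels row-major into a grid.

    Panels are padded (bottom/right) to the largest panel size; the layout
    is fully deterministic. With ``n`` panels and ``c`` columns the grid has
    ``ceil(n / c)`` rows; a short last row is padded with background.
    """
    if not items:
        raise ValueError("render_grid requires at least one panel")
    if columns < 1:
        raise ValueError("columns must be >= 1")
    bg = hex_to_rgb(background)
    ph = max(p.shape[0] for p in items)
    pw = max(p.shape[1] for p in items)
    n = len(items)
    nrows = -(-n // columns)
    H = nrows * ph + (nrows + 1) * margin_px
    W = columns * pw + (columns + 1) * margin_px
    canvas = np.empty((H, W, 3), dtype=float)
    canvas[:] = bg
    for i, panel in enumerate(items):
        gr, gc = divmod(i, columns)
        r0 = margin_px + gr * (ph + margin_px)
        c0 = margin_px + gc * (pw + margin_px)
        h, w = panel.shape
        canvas[r0 : r0 + h, c0 : c0 + w] = panel.rgb
    out = RenderedImage(canvas)
    out.annotate("title", layout=(nrows, columns), n_panels=n)
    return out
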