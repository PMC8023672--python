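"""Deterministic synthetic multiplexed-imaging fixtures with planted ground truth.

The generator emulates the three inputs of a multiplexed-imaging analysis —
segmentation masks, multi-channel stacks and a cell table — with known cell
types, so every rendering, measurement and gating operation is testable
offline. Cells are filled discs placed by rejection sampling without
overlap: discs have closed-form pixel counts and trivially verifiable
disjointness, which is what testing needs; tissue realism is deliberately
out of scope.

Intensities follow a type x marker signature matrix on a constant
background; optional noise is truncated Gaussian (clipped at 0 to keep
intensities non-negative) or Poisson (each pixel replaced by a Poisson draw
with the clean value as mean). With no noise, per-cell mean measurement
recovers the signature matrix exactly — the core round-trip of the package.

All randomness flows from a single seeded generator per call; there is no
global random state, and a fixed seed reproduces every output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import CellTable, ImageCollection, ImageStack, SegmentationMask
from .transforms import measure_cells

__all__ = [
    "SimulationSpec",
    "DEFAULT_SIGNATURES",
    "generate_masks",
    "generate_stacks",
    "generate_cell_table",
    "make_t1d_like_scenario",
]

# Marker panel and type x marker mean intensities for the default scenario:
# PIN marks beta (insulin-producing islet) cells, CD4 helper T cells, CD8a
# cytotoxic T cells, SYP (synaptophysin) all endocrine islet cells, H3 all
# nuclei. Values are ion-count-scale means typical of IMC data.
DEFAULT_MARKERS = ["PIN", "CD4", "CD8a", "SYP", "H3"]
DEFAULT_SIGNATURES = {
    "beta": {"PIN": 5.0, "CD4": 0.0, "CD8a": 0.0, "SYP": 3.0, "H3": 1.0},
    "alpha": {"PIN": 0.0, "CD4": 0.0, "CD8a": 0.0, "SYP": 3.0, "H3": 1.0},
    "Th": {"PIN": 0.0, "CD4": 4.0, "CD8a": 0.0, "SYP": 0.0, "H3": 1.0},
    "Tc": {"PIN": 0.0, "CD4": 0.0, "CD8a": 4.0, "SYP": 0.0, "H3": 1.0},
    "other": {"PIN": 0.0, "CD4": 0.0, "CD8a": 0.0, "SYP": 0.0, "H3": 1.0},
}


@dataclass
class SimulationSpec:
    """Parameters of one synthetic image set.

    ``proportions`` must sum to 1; ``signatures`` maps each type to
    non-negative mean intensities per marker. ``noise`` is one of
    ``none``, ``gaussian`` (additive N(0, sigma^2) truncated at 0) or
    ``poisson``. ``max_attempts`` bounds disc rejection sampling per image.
    """

    n_images: int = 3
    shape: tuple[int, int] = (256, 256)
    n_cells: int = 200
    radius_range: tuple[int, int] = (2, 4)
    proportions: dict[str, float] = field(
        default_factory=lambda: {"beta": 0.35, "alpha": 0.2, "Tc": 0.1, "Th": 0.1, "other": 0.25}
    )
    signatures: dict[str, dict[str, float]] = field(
        default_factory=lambda: {t: dict(m) for t, m in DEFAULT_SIGNATURES.items()}
    )
    markers: list[str] = field(default_factory=lambda: list(DEFAULT_MARKERS))
    noise: str = "none"
    noise_sigma: float = 0.1
    background: float = 0.0
    pixel_size_um: float = 1.0
    seed: int = 0
    name_prefix: str = "img"
    max_attempts: int = 200

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.radius_range[0] < 1 or self.radius_range[0] > self.radius_range[1]:
            raise ValueError(f"invalid radius range {self.radius_range}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell type proportions must sum to 1, got {total}")
        if self.noise not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.background < 0:
            raise ValueError("background intensity must be >= 0")
        for t, sig in self.signatures.items():
            if any(v < 0 for v in sig.values()):
                raise ValueError(f"signature for type {t!r} has negative entries")

    @property
    def image_names(self) -> list[str]:
        width = len(str(self.n_images))
        return [f"{self.name_prefix}{i:0{width}d}" for i in range(1, self.n_images + 1)]


def _disc_offsets(radius: int) -> np.ndarray:
    """(k, 2) integer offsets with dr^2 + dc^2 <= radius^2 (boundary included)."""
    rng = np.arange(-radius, radius + 1)
    dr, dc = np.meshgrid(rng, rng, indexing="ij")
    inside = dr * dr + dc * dc <= radius * radius
    return np.stack([dr[inside], dc[inside]], axis=1)


def _place_discs(
    rng: np.random.Generator, spec: SimulationSpec
) -> tuple[np.ndarray, list[dict]]:
    """Rejection-sample non-overlapping discs; label 1..n in placement order."""
    rows, cols = spec.shape
    labels = np.zeros((rows, cols), dtype=np.int64)
    placed = []
    r_min, r_max = spec.radius_range
    for i in range(1, spec.n_cells + 1):
        ok = False
        for _ in range(spec.max_attempts):
            radius = int(rng.integers(r_min, r_max + 1))
            cr = int(rng.integers(0, rows))
            cc = int(rng.integers(0, cols))
            off = _disc_offsets(radius)
            rr = off[:, 0] + cr
            cc_ = off[:, 1] + cc
            keep = (rr >= 0) & (rr < rows) & (cc_ >= 0) & (cc_ < cols)
            rr, cc_ = rr[keep], cc_[keep]
            if rr.size and not labels[rr, cc_].any():
                labels[rr, cc_] = i
                placed.append(
                    {"object_id": i, "centre_row": cr, "centre_col": cc, "radius": radius}
                )
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place cell {i}/{spec.n_cells} after {spec.max_attempts} "
                "attempts; reduce n_cells or the cell radius"
            )
    return labels, placed


def generate_masks(spec: SimulationSpec) -> tuple[ImageCollection, pd.DataFrame]:
    """Generate segmentation masks with planted cell types.

    Returns the mask collection and a ground-truth table with one row per
    cell: image_name, object_id, cell_type, centre (row, col) and radius.
    Discs are pairwise disjoint, clipped at image borders and labelled in
    placement order; a fixed seed reproduces the masks bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    types = sorted(spec.proportions)
    probs = np.array([spec.proportions[t] for t in types])
    entries = {}
    truth_rows = []
    for name in spec.image_names:
        labels, placed = _place_discs(rng, spec)
        assigned = rng.choice(types, size=len(placed), p=probs)
        entries[name] = SegmentationMask(labels, pixel_size_um=spec.pixel_size_um)
        for rec, cell_type in zip(placed, assigned):
            truth_rows.append({"image_name": name, **rec, "cell_type": str(cell_type)})
    truth = pd.DataFrame(
        truth_rows,
        columns=["image_name", "object_id", "cell_type", "centre_row", "centre_col", "radius"],
    )
    return ImageCollection(entries), truth


def generate_stacks(
    masks: ImageCollection, truth: pd.DataFrame, spec: SimulationSpec
) -> ImageCollection:
    """Paint marker intensities onto the masks per the signature matrix.

    Inside each object every channel takes ``background + signature[type,
    marker]``; elsewhere the background. Gaussian noise adds truncated
    N(0, sigma^2); Poisson noise replaces each pixel by a Poisson draw with
    the clean value as mean (so a clean value of 0 stays exactly 0).
    """
    rng = np.random.default_rng(spec.seed + 1)
    planted_types = set(truth["cell_type"].unique())
    missing = planted_types - set(spec.signatures)
    if missing:
        raise KeyError(f"signature matrix missing planted types: {sorted(missing)}")

    entries = {}
    for name in masks.names:
        labels = masks[name].labels
        rows, cols = labels.shape
        pixels = np.full((rows, cols, len(spec.markers)), float(spec.background))
        sub = truth[truth["image_name"] == name]
        top = int(labels.max(initial=0))
        lut = np.zeros((top + 1, len(spec.markers)))
        for _, rec in sub.iterrows():
            sig = spec.signatures[rec["cell_type"]]
            lut[int(rec["object_id"])] = [sig.get(m, 0.0) for m in spec.markers]
        pixels += lut[labels]
        if spec.noise == "gaussian":
            pixels = np.clip(pixels + rng.normal(0.0, spec.noise_sigma, pixels.shape), 0.0, None)
        elif spec.noise == "poisson":
            pixels = rng.poisson(pixels).astype(float)
        entries[name] = ImageStack(pixels, spec.markers, pixel_size_um=spec.pixel_size_um)
    return ImageCollection(entries, element_metadata=masks.element_metadata)


def generate_cell_table(
    masks: ImageCollection, stacks: ImageCollection, truth: pd.DataFrame
) -> CellTable:
    """Measure every image and attach the ground-truth cell types.

    Expression comes from per-object mean measurement of the stacks; the
    metadata carries ``cell_type`` (ground truth), ``area_px`` and centroid.
    Keys exactly enumerate the mask objects.
    """
    parts = []
    markers = None
    for name in masks.names:
        t = measure_cells(stacks[name], masks[name], image_name=name)
        markers = t.marker_names
        parts.append(t.data)
    data = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    merged = data.merge(
        truth[["image_name", "object_id", "cell_type"]], on=["image_name", "object_id"], how="left"
    )
    merged["cell_type"] = pd.Categorical(merged["cell_type"].astype(str))
    return CellTable(merged, markers or [])


# Per-group cell-type proportions of the disease-course scenario: the
# beta-cell fraction declines monotonically from healthy through recent
# onset to long-duration disease, while T-cell (Tc/Th) infiltration peaks
# at recent onset.
_SCENARIO_GROUPS = {
    "healthy": {"beta": 0.50, "alpha": 0.20, "Tc": 0.03, "Th": 0.03, "other": 0.24},
    "recent_onset": {"beta": 0.30, "alpha": 0.20, "Tc": 0.15, "Th": 0.15, "other": 0.20},
    "long_duration": {"beta": 0.08, "alpha": 0.22, "Tc": 0.06, "Th": 0.06, "other": 0.58},
}


def make_t1d_like_scenario(
    seed: int = 0,
    images_per_group: int = 3,
    base_spec: SimulationSpec | None = None,
) -> dict:
    """Full fixture set mirroring a three-condition disease-course study.

    Three groups of images (healthy, recent onset, long duration) with a
    monotonically decreasing beta-cell proportion and a peak of cytotoxic
    (Tc) / helper (Th) T-cell density in the middle group. Returns a dict
    with ``masks``, ``stacks``, ``cells`` (measured CellTable with ground
    truth), ``truth``, ``groups`` (image -> group) and ``spec_by_group``.
    Element metadata of masks and stacks carries the ``condition`` label.
    """
    if base_spec is None:
        base_spec = SimulationSpec()
    mask_entries: dict[str, SegmentationMask] = {}
    truth_parts = []
    groups: dict[str, str] = {}
    spec_by_group: dict[str, SimulationSpec] = {}
    stacks_entries: dict[str, ImageStack] = {}
    for gi, (group, props) in enumerate(_SCENARIO_GROUPS.items()):
        spec = replace(
            base_spec,
            n_images=images_per_group,
            proportions=dict(props),
            seed=seed + 1000 * (gi + 1),
            name_prefix=f"{group}_",
        )
        spec_by_group[group] = spec
        g_masks, g_truth = generate_masks(spec)
        g_stacks = generate_stacks(g_masks, g_truth, spec)
        for name in g_masks.names:
            mask_entries[name] = g_masks[name]
            stacks_entries[name] = g_stacks[name]
            groups[name] = group
        truth_parts.append(g_truth)
    truth = pd.concat(truth_parts, ignore_index=True)
    meta = pd.DataFrame({"condition": [groups[n] for n in mask_entries]}, index=list(mask_entries))
    masks = ImageCollection(mask_entries, element_metadata=meta)
    stacks = ImageCollection(stacks_entries, element_metadata=meta.copy())
    cells = generate_cell_table(masks, stacks, truth)
    return {
        "masks": masks,
        "stacks": stacks,
        "cells": cells,
        "truth": truth,
        "groups": groups,
        "spec_by_group": spec_by_group,
    }
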