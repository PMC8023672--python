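"""Hierarchical gating on marker expression with image-backed visualization
and selection export.

A gate is a closed interval on one marker; a gate sequence applies gates in
order, each acting on the survivors of the previous one — the programmatic
equivalent of hierarchical cytometry gating. Selections can be rendered as
coloured objects on segmentation masks or as outlines on composites, and
exported as CSV plus a YAML provenance sidecar that records the exact gates
applied.

Gate bounds are closed: a value exactly at a bound is kept. Values tied at
thresholds are common after transform steps, so the convention must be
pinned and is documented here. Gating operates on the expression matrix as
stored; any upstream transformation belongs in the provenance record.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import CellTable, ImageCollection, ColorSpec
from .io import export_cells
from .rendering import (
    CategoricalPalette,
    RenderedImage,
    colorize_mask_by_metadata,
    composite_pixels,
    outline_cells,
)

__all__ = [
    "Gate",
    "GateSequence",
    "Selection",
    "apply_gate_sequence",
    "visualize_selection",
    "export_selection",
    "read_gate_sequence",
]

SOFT_MARKER_CAP = 24


@dataclass(frozen=True)
class Gate:
    """Closed interval [lower, upper] on one marker."""

    marker: str
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError(f"gate on {self.marker!r}: lower {self.lower} > upper {self.upper}")


@dataclass
class GateSequence:
    """Ordered gates defining one population.

    Markers may repeat (successive tightening). More than 24 gates warns but
    runs: the cap is a GUI convention of interactive gating tools, not a
    mathematical limit.
    """

    gates: list[Gate]
    label: str = "selection"

    def __post_init__(self):
        if len(self.gates) > SOFT_MARKER_CAP:
            warnings.warn(
                f"gate sequence has {len(self.gates)} gates, above the usual "
                f"cap of {SOFT_MARKER_CAP} markers; proceeding anyway",
                UserWarning,
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "gates": [
                {
                    "marker": g.marker,
                    "min": None if g.lower == -math.inf else float(g.lower),
                    "max": None if g.upper == math.inf else float(g.upper),
                }
                for g in self.gates
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GateSequence":
        gates = [
            Gate(
                marker=str(g["marker"]),
                lower=-math.inf if g.get("min") is None else float(g["min"]),
                upper=math.inf if g.get("max") is None else float(g["max"]),
            )
            for g in d.get("gates", [])
        ]
        return cls(gates=gates, label=str(d.get("label", "selection")))


@dataclass
class Selection:
    """Cells passing a gate sequence, with per-gate survivor counts."""

    cells: CellTable
    provenance: GateSequence
    survivor_counts: list[int] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return self.cells.n_cells


def apply_gate_sequence(cells: CellTable, gs: GateSequence) -> Selection:
    """Filter cells sequentially through the gates.

    A cell survives a gate iff ``lower <= expression[cell, marker] <= upper``.
    The per-gate survivor counts are recorded (necessarily non-increasing);
    the final subset preserves input row order. An empty gate list keeps
    every cell.
    """
    unknown = [g.marker for g in gs.gates if g.marker not in cells.marker_names]
    if unknown:
        raise KeyError(f"unknown gate markers: {sorted(set(unknown))}")
    keep = np.ones(cells.n_cells, dtype=bool)
    counts = []
    for gate in gs.gates:
        values = cells.data[gate.marker].to_numpy(dtype=float)
        keep &= (values >= gate.lower) & (values <= gate.upper)
        counts.append(int(keep.sum()))
    return Selection(cells=cells.subset(keep), provenance=gs, survivor_counts=counts)


def visualize_selection(
    sel: Selection,
    masks: ImageCollection,
    stacks: ImageCollection | None = None,
    mode: str = "mask_objects",
    palette: CategoricalPalette | None = None,
    composite_spec: ColorSpec | None = None,
    outline_thickness: int = 1,
) -> list[RenderedImage]:
    """Render the selected cells on their images.

    ``mask_objects`` colours selected objects on the segmentation masks
    (everything else white on black); ``outlines`` draws selection outlines
    on channel composites and therefore needs ``stacks`` and a
    ``composite_spec``. Returns one image per mask (collection order); an
    empty selection returns an empty list with a warning.
    """
    if mode not in ("mask_objects", "outlines"):
        raise ValueError(f"unknown mode {mode!r}")
    if sel.n_selected == 0:
        warnings.warn("selection is empty; nothing to visualize", UserWarning, stacklevel=2)
        return []
    if palette is None:
        palette = CategoricalPalette(colors={"yes": (1.0, 0.0, 0.0)})
    images_with_cells = set(sel.cells.data["image_name"].unique())

    rendered = []
    for name in masks.names:
        if name not in images_with_cells:
            continue
        mask = masks[name]
        sub = sel.cells.for_image(name)
        if mode == "mask_objects":
            flagged = sub.data.copy()
            flagged["selected"] = "yes"
            flagged_table = CellTable(flagged, sel.cells.marker_names)
            img = colorize_mask_by_metadata(mask, flagged_table, name, "selected", palette)
        else:
            if stacks is None or name not in stacks:
                raise ValueError(f"outlines mode requires a stack for image {name!r}")
            if composite_spec is None:
                raise ValueError("outlines mode requires a composite ColorSpec")
            base = composite_pixels(stacks[name], composite_spec)
            selected_ids = {int(i) for i in sub.data["object_id"]}
            img = outline_cells(
                base,
                mask,
                thickness=outline_thickness,
                default_color=palette["yes"] if "yes" in palette else (1.0, 1.0, 1.0),
                restrict_to=selected_ids,
            )
        img.annotate("title", image=name, selection=sel.provenance.label, n_cells=sub.n_cells)
        rendered.append(img)
    return rendered


def export_selection(sel: Selection, path) -> tuple[Path, Path]:
    """Write the selected cells as CSV plus a YAML provenance sidecar.

    The sidecar serializes the gate sequence (``{marker, min, max}`` items
    plus label) and the survivor counts, so re-applying the recorded gates
    to the original table reproduces the exported keys exactly.
    Returns ``(csv_path, provenance_path)``.
    """
    csv_path = Path(path)
    export_cells(sel.cells, csv_path)
    prov_path = csv_path.with_suffix(csv_path.suffix + ".provenance.yaml")
    prov = sel.provenance.to_dict()
    prov["survivor_counts"] = list(sel.survivor_counts)
    prov["n_selected"] = sel.n_selected
    with open(prov_path, "w") as fh:
        yaml.safe_dump(prov, fh, sort_keys=False)
    return csv_path, prov_path


def read_gate_sequence(path) -> GateSequence:
    """Load a gate sequence from its YAML schema (list of {marker, min, max})."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return GateSequence.from_dict(d)
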