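# cytoviz

Visualization of highly multiplexed imaging data at pixel and cell level.

Highly multiplexed imaging technologies — imaging mass cytometry (IMC),
MIBI, CODEX, t-CyCIF and similar — measure dozens of protein markers *in
situ*, producing for each tissue region a multi-channel intensity stack
(one channel per marker) and, after segmentation, an integer-labelled cell
mask. `cytoviz` is a toolkit for inspecting that data:

* **Cell-level views** — colour segmentation masks by per-cell marker
  expression (continuous colour ramp) or by categorical metadata such as
  cell type (palette; unselected cells white on black).
* **Pixel-level views** — blend up to six channels into an RGB composite;
  each channel gets a colour and a background/contrast/gamma adjustment,
  contributions add and clip at 1.
* **Segmentation QC** — outline cells on composites, with outlines
  optionally coloured by cell metadata.
* **Image selection** — rank images by the density of chosen cell types
  (cells per mm² or per megapixel) and pick the top image per condition.
* **Hierarchical gating** — select cell populations through sequences of
  closed-interval gates on marker expression, verify them on the images,
  and export the selection with full gate provenance.
* **Synthetic fixtures** — a seeded generator of masks, stacks and cell
  tables with planted ground-truth cell types, so the entire pipeline is
  testable offline.

The in-memory model is small: an `ImageStack` (rows × cols × channels, one
named channel per marker), a `SegmentationMask` (integer labels, 0 =
background), an `ImageCollection` (ordered, uniquely named stacks or masks
with per-image metadata) and a `CellTable` (cells × markers expression
matrix keyed by `(image_name, object_id)`, plus metadata columns). Per-cell
expression is the arithmetic mean of each channel over the cell's pixels —
the standard "mean ion counts per marker" read-out.

## Worked example

```python
import cytoviz as cv

# synthetic three-condition study: beta-cell loss with T-cell infiltration
scenario = cv.make_t1d_like_scenario(seed=42, images_per_group=2)
cells, masks = scenario["cells"], scenario["masks"]
print(f"{cells.n_cells} cells across {len(masks)} images, markers: {cells.marker_names}")

# rank images by density of cytotoxic (Tc) and helper (Th) T cells per condition
ranking = cv.rank_images(cells, masks, types={"Tc", "Th"},
                         type_column="cell_type", group_column="condition")
print(ranking.table[["image_name", "group", "count", "density", "selected"]].to_string(index=False))

# hierarchical gating: CD8a-high, CD4-low selects the cytotoxic T cells
gates = cv.GateSequence([cv.Gate("CD8a", lower=3.5, upper=4.5),
                         cv.Gate("CD4", upper=0.5)], label="cytotoxic_T")
sel = cv.apply_gate_sequence(cells, gates)
print(f"selected {sel.n_selected} cells; survivor counts {sel.survivor_counts}")
```

Output:

```
1200 cells across 6 images, markers: ['PIN', 'CD4', 'CD8a', 'SYP', 'H3']
     image_name         group  count    density  selected
      healthy_2       healthy     14 213.623047      True
      healthy_1       healthy     13 198.364258     False
long_duration_1 long_duration     25 381.469727      True
long_duration_2 long_duration     16 244.140625     False
 recent_onset_1  recent_onset     61 930.786133      True
 recent_onset_2  recent_onset     57 869.750977     False
selected 98 cells; survivor counts [98, 98]
```

The density column is cells per mm² (each image is 256 × 256 px at
1 µm/px, i.e. 0.0655 mm²). T-cell density peaks in the recent-onset group,
as planted; `selected` flags the top-density image of each condition. The
gate sequence recovers exactly the 98 planted cytotoxic T cells: survivor
counts stay at 98 after each gate because on noise-free data the CD8a gate
alone is already exact.

To render the views:

```python
palette = cv.CategoricalPalette(colors={"beta": "#ff0000", "alpha": "#ffa500",
                                        "Tc": "#00ff00", "Th": "#0000ff",
                                        "other": "#888888"})
img = cv.colorize_mask_by_metadata(masks["recent_onset_1"], cells,
                                   "recent_onset_1", "cell_type", palette)
img = cv.add_scale_bar(img, length_um=20)
cv.write_rendered(img, "recent_onset_1_celltypes.png")

spec = cv.ColorSpec({"PIN":  cv.ChannelDisplay(color=(1, 1, 0), contrast=10),
                     "CD4":  cv.ChannelDisplay(color=(0, 0, 1), contrast=8),
                     "CD8a": cv.ChannelDisplay(color=(1, 0, 0), contrast=10)})
comp = cv.composite_pixels(scenario["stacks"]["recent_onset_1"], spec)
cv.write_rendered(comp, "recent_onset_1_composite.png")
```

## Command line

The same pipelines are scriptable via the `cytoviz` command:

```sh
cytoviz make-fixtures --out fixtures --seed 1        # synthetic TIFFs + CSV + ground truth
cytoviz measure --config config.yaml --out cells.csv # per-cell mean intensities
cytoviz render  --config config.yaml --out renders   # PNG per image + grid + manifest
cytoviz gate    --config config.yaml --gates gates.yaml --out selection
```

Configs are YAML; flags override config keys; every command is
deterministic given config + seed (the manifest records a config hash and
reruns are byte-identical).

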