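# Methods

## Data model and conventions

All images use the `(row, col)` convention, 0-based, origin at the top
left, matching raster file order. An `ImageStack` holds finite,
non-negative intensities in arbitrary units (typically ion counts for IMC);
a `SegmentationMask` holds exact integer labels with 0 as background —
labels are never rescaled on IO, because scaling a label image corrupts
object identities. An `ImageCollection` is an ordered mapping from unique
image names to entries of a single kind; stacks in one collection must
share identical channel names in identical order. Dimensions are *not*
required to be identical across images in a collection. Pairing of stacks,
masks and cell rows is by exact image-name string equality; fuzzy matching
is deliberately absent because a silently mismatched stack/mask pair is the
principal QC hazard of this workflow. Cell rows citing object ids missing
from the paired mask are tolerated at pairing time and surfaced in the
report; rendering paints such orphans nowhere and records a warning
annotation.

## Measurement

Per-cell expression is the arithmetic mean of each channel over the cell's
member pixels (computed with `scipy.ndimage` labelled statistics), plus
`area_px` and the centroid in pixel units. This is the standard mean-counts
read-out; no morphological features beyond area/centroid are extracted.

## Normalization and scaling

`normalize` maps each channel by `clip((v − lo)/(hi − lo), 0, 1)`, with
`lo/hi` either the channel min/max or two percentiles (linear-interpolation
definition, pinned for reproducibility), computed per image (`separate`,
the default) or pooled over the collection (`joint`). A degenerate channel
(`hi == lo`) maps to all zeros. Min–max/separate is idempotent.
`scale_intensity` multiplies named channels by positive factors without
clipping; clipping is a render-time decision, so scaling composes
multiplicatively and commutes with channel reordering.

## Rendering

*Mask colouring.* Continuous features map to a colour ramp by
`t = clip((v − lo)/(hi − lo), 0, 1)` with piecewise-linear interpolation
**in RGB space** — simple and deterministic; perceptual colour spaces would
look slightly different but add a dependency and a tie to a specific
implementation. The default feature range is the min/max over the plotted
cells of the current image; pass an explicit range for cross-image
comparability. A degenerate range uses the first ramp colour. Categorical
columns map through a palette; cells outside the plotted subset or missing
from the table get the missing colour (default white), background is black
— the usual convention for cell-type overlays.

*Composites.* Each of at most six channels is adjusted in the pinned order
multiply-by-contrast → add-background → clip-at-0 → gamma → linear range
map into [0, 1], then contributes its value times its colour. When no
range is given, the adjusted channel's own min/max is used, matching how
composite viewers autoscale. Contributions are summed in sorted channel
order (float addition is not bit-commutative, and the blend must be
invariant to the request order) and clipped at 1. Additive blending was
chosen over screen blending because it reproduces the familiar appearance
of marker overlays where co-occurring markers mix (yellow + blue, etc.).
The six-channel cap is a hard error: beyond six, colour collisions make
composites misleading.

*Outlines.* A boundary pixel is an object pixel with at least one
8-connected in-image neighbour of a different label; image-border pixels
are not boundary unless an in-image neighbour differs. Thickness grows by
iterative inward peeling (outline the boundary, remove it, repeat), so
outlines never spill outside their object. The implementation is
vectorized shifts; tests verify it pixel-for-pixel against an exhaustive
double-loop oracle.

*Scale bars and grids.* A scale bar spans `round(length_um /
pixel_size_um)` pixels in the bottom-left margin; requesting a bar wider
than the image is an error. Grids place panels row-major, padded to the
largest panel; the layout is fully deterministic. Legends are emitted as
structured annotations rather than rasterized text; the annotation record
is the API.

*PNG output.* Values must already be in [0, 1] (clipping is always an
explicit caller decision); quantization is `round(v·255)` to 8-bit, so a
re-read differs by at most 1/255 per channel.

## Density ranking

Density is (matching cells) / (full image area), reported per mm² when the
pixel size is known and per megapixel otherwise. The denominator is the
whole image, not a tissue area — no tissue segmentation step exists in
this package, which can overstate differences between images with very
different tissue coverage. Ranking is descending density with ties broken
by ascending image name; the deterministic order is a hard requirement.
Images with missing group metadata are ranked in a reported `"NA"` group.

## Gating

Gates are closed intervals; values exactly at a bound are kept. The choice
matters because ties at thresholds are common after transform steps, and it
is pinned and tested. Gates apply sequentially; survivor counts are
recorded per gate and are non-increasing; for gates on distinct markers the
conjunction is order-invariant. The 24-marker cap is a warning, not an
error — it is a GUI convention of interactive gating tools, not a
mathematical limit. Only per-marker interval gates exist; polygon/ellipse
gates and automatic threshold finding are out of scope. Gating operates on
the expression matrix as stored; any upstream transformation should be
applied first and noted in the provenance sidecar, which records the full
gate sequence as YAML so a selection can be replayed exactly.

## Synthetic data

Cells are filled discs (boundary included: pixels with
`dr² + dc² ≤ r²`), placed by rejection sampling without overlap, clipped
at image borders, labelled in placement order. Discs rather than realistic
cell shapes: closed-form pixel counts and trivially verifiable disjointness
are what testing the rendering/measurement/gating logic needs. Defaults:
3 images of 256 × 256 px at 1 µm/px, 200 cells per image, radii 2–4 px,
five markers (PIN, CD4, CD8a, SYP, H3) and five cell types (beta, alpha,
Th, Tc, other) whose signature matrix gives each type one or two
distinguishing markers at ion-count-scale means (e.g. beta: PIN = 5,
SYP = 3, H3 = 1) — chosen as a minimal caricature of a pancreatic-islet
panel. Noise models: none (exact), truncated Gaussian (clipped at 0 to
keep intensities non-negative; default σ = 0.1), or Poisson (each pixel
replaced by a Poisson draw with the clean value as mean, emulating count
noise; a clean 0 stays exactly 0). All randomness flows from one
`numpy` generator seeded per call; fixed seeds reproduce every output bit
for bit.

The disease-course scenario builds three condition groups — healthy,
recent onset, long duration — with a monotonically decreasing beta-cell
proportion (0.50 → 0.30 → 0.08) and T-cell (Tc + Th) proportions peaking
in the middle group (0.06 → 0.30 → 0.12), a caricature of beta-cell loss
with transient immune infiltration. What the generator does **not**
emulate: tissue architecture (islets, vessels), cell-shape variability,
channel spillover, autofluorescence/background structure, and spatial
correlation between neighbouring cells. Tests passing on these fixtures
therefore validate the *logic* of measurement, rendering and gating, not
robustness to real-tissue artefacts.

## Numerical and testing choices

Per-cell means on noise-free fixtures must match the signature matrix to
1e-12 relative (they are exact in practice, since every member pixel holds
the same value). The Poisson gating check widens gates to ±4 standard
errors of a cell mean, `4·sqrt(mean/area)` with the 30-px minimum area as
the conservative denominator; by the CLT a conforming cell escapes such a
gate with probability ≈ 1e-4, so the ≥ 0.95 recall requirement carries a
negligible flake budget at the tested sizes. Border-clipped discs smaller
than 30 px are excluded from that guarantee. Problem sizes throughout the
suite (dozens of images of 32–256 px, hundreds of cells) keep the whole
test run in seconds on one CPU while still exercising every code path;
oracle comparisons (outline double-loop, gating row filter, measurement
pixel loop) are exhaustive at those sizes.
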