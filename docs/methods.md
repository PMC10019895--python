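# Methods

## Overview

`imcseg` segments cells in imaging-mass-cytometry (IMC) acquisitions and
quantifies them into single-cell tables. An IMC region of interest (ROI)
arrives as a registered stack of 16-bit single-channel images, one per
metal-tagged marker, holding raw ion counts. The pipeline is:

1. **Compositing** — sum the selected membrane markers into one plane, take
   the nuclei stain as the other, denoise both (median filter, then Gaussian
   smoothing), apply multiplicative display gains, clip to [0, 1].
2. **Patch-wise U-Net** — tile the two-plane composite into 128×128 patches,
   run each through a U-shaped convolutional network that outputs a per-pixel
   cell probability, and reassemble the full-size probability map.
3. **Binarization and post-processing** — threshold at 0.5 (ties to
   foreground), label connected components, then (a) remove objects with no
   nuclei signal, (b) remove 1–2-pixel specks, (c) fill enclosed holes.
4. **Quantification** — per labeled cell: centroid, pixel count, and the mean
   and median of every marker measured on the *raw* stack. Two CSV files are
   written (mean and median); the median table exists because isolated
   aberrant hot pixels are endemic to ion-count imaging and wreck means.
5. **Evaluation** — geometric (per-cell IoU against ground truth) and
   biological (real-cell percentage, exclusive-marker double-positive rate).

## The network

Classic U-Net: `depth` contracting blocks (two 3×3 convolutions + ReLU, then
2×2 max-pool), filter width doubling per block from `base_filters`; an
expansive path with 2×2 up-convolutions, skip concatenation, and two 3×3
convolutions per block; a final 1×1 convolution with logistic activation.

Deviations and choices worth knowing:

- **Same-padding convolutions.** The original U-Net uses valid convolutions
  and crops skips; here output size must equal input size because 128×128
  tile predictions are reassembled into the original image, so convolutions
  are zero-padded and skips concatenate without cropping.
- **Loss.** Per-pixel binary cross-entropy with natural log, predictions
  clamped to [1e-7, 1−1e-7]. Training uses the numerically stable combined
  sigmoid/BCE gradient `(p − y)/N` at the logit.
- **Optimization.** Adam at its standard settings (lr 1e-3, β₁ 0.9,
  β₂ 0.999), batch size 16, up to `max_epochs` epochs with early stopping on
  a held-out validation split (default fraction 0.1, patience configurable);
  the best-epoch weights are restored.
- **Implementation.** The network (forward, backward, optimizer) is written
  in NumPy, float32, with 3×3 convolutions computed as nine batched
  matrix-products against shifted views of the padded input — this keeps
  memory traffic low and runs entirely on BLAS. Backprop is verified against
  central finite differences in double precision in the test suite. Training
  is exactly reproducible from a seed on a given machine.
- **Profiles.** `base_filters=64` is the classic width; the benchmarks and
  tests use a CPU-scale profile (`base_filters=16`, ≤25 epochs, ~200 training
  patches) chosen so a full train/evaluate cycle stays in the minutes range
  on one core.

## Compositing choices

The field practice this emulates is interactive: a microscopist picks
markers, sums membranes, and turns up brightness until the image "looks
right". Codifying that required decisions:

- Median filter first (radius 1 → 3×3 window), Gaussian blur second
  (σ = 1.0): the median pass removes isolated hot pixels before smoothing
  could smear them.
- Gain normalization reference defaults to the 99.9th percentile of the
  filtered plane (robust to hot pixels); a flag switches to the absolute max.
- Default gains: nuclei ×2.5, membrane ×6.0 — inside the ×2–×3 and up-to-×10
  ranges that suit typical nuclei and membrane count levels.
- Filters are applied to the *summed* membrane plane, not per channel, and
  clipping happens once after gain.
- Optional per-channel gains from the panel config reweight raw channels
  before summation (e.g. to boost a dim marker relative to a bright one);
  the plane-level nuclei/membrane gains then set overall brightness.

## Patching

Non-overlapping tiles in row-major order, zero-padded at the right/bottom
edges with the padding recorded, so split → merge is the exact identity for
every image size. Zero padding matches the background semantics of the
binary target. Known limitation: no overlap-blending, so a cell crossing a
tile boundary is predicted from two half-contexts; on the synthetic
benchmark this shows up as a mild IoU penalty for boundary-straddling cells.

## Post-processing

Step order is: nuclei filter, then size filter, then hole filling.

- "Shows no nuclei signal" is operationalized as: no pixel of the object
  exceeds a nuclei threshold on the raw nuclei channel; the threshold
  defaults to Otsu's value computed on that channel, overridable.
- Connected components use 8-connectivity by default (biological blobs touch
  diagonally); labels are assigned in raster-scan order of first pixel and
  compacted to 1..K after every step.
- Hole filling is per label: a pocket jointly enclosed by two different
  cells stays open, and only background pixels are ever claimed, so the
  step never changes the cell count.
- Touching cells are *not* split (no watershed): the network output is a
  semantic mask, so adjacent cells that merge into one component stay
  merged. This is the main known failure mode and is exactly what the
  double-positive metric detects.

## Evaluation metrics

- **Per-cell IoU.** For each ground-truth cell, the Jaccard index against
  the predicted object sharing the most pixels with it (ties to the smaller
  predicted label); unmatched truth cells score 0; predicted objects that
  match nothing do not enter the mean. The patch score is the unweighted
  mean over truth cells; the benchmark reports the mean over patches. The
  matching rule changes the number, which is why it is pinned down here.
- **Real cells.** An object counts as real iff its mean nuclei intensity
  reaches 10% of the nuclei image's grayscale range (robust maximum =
  99.9th-percentile intensity, so hot pixels cannot stretch the scale). A
  plain low percentile of foreground nuclei values was rejected: on sparse
  count data a large share of in-cell nuclei pixels are exact zeros, which
  drives such a threshold to 0 and makes every object "real".
- **Double positives.** A cell is positive for a marker iff its mean raw
  intensity exceeds that marker's threshold — by default Otsu's threshold on
  the per-cell mean distribution, overridable per marker. The rate of cells
  positive for both members of an exclusive pair (CD3/CD20, PanKeratin/CD8)
  estimates segmentation/gating error, since single cells cannot co-express
  these lineage markers.

## Synthetic scenes

The generator produces ROIs with exact ground truth: randomly oriented
ellipse cells (semi-axes uniform in 5–9 px) placed by rejection sampling
with a guaranteed ≥3 px border gap (via bounding circles), a bright nucleus
disk (0.6 of the cell radii) on the DNA channel at mean 40 counts, membrane
markers as boundary rings (outer 25% of the radius), cytoplasmic markers as
filled footprints, Poisson noise everywhere over a 0.5-count background,
and rare hot pixels (rate 1e-4, value 500). Default panel: DNA plus
CD3/CD8 T cells, CD20 B cells, CD68 macrophages, PanKeratin epithelium —
yielding the exclusive pairs (CD3, CD20) and (PanKeratin, CD8) with true
co-expression exactly zero. Default scene: 256×256 with 60 cells (~14%
foreground).

What the scenes do *not* emulate: tissue architecture, spillover/isotope
crosstalk, cell-shape irregularity beyond ellipses, densely touching cell
masses, and intensity heterogeneity within a cell type. Passing benchmarks
on these scenes therefore demonstrates that the pipeline's machinery is
correct and self-consistent — not that the trained weights transfer to real
tissue, which requires training on curated real patches.

## Benchmark problem sizes

The benchmarks (`imcseg.benchmark`, driven by `scripts/acceptance.py` and
the acceptance tests) use: 50 training scenes of 256×256 (= 200 patches of
128×128, 10% held out for validation), ≤25 epochs at patience 10; 90
held-out evaluation patches from unseen scenes; 18 scenes with 10%
anucleate objects for the real-cell metric; 18 two-lineage scenes for the
double-positive metric. All scene seeds derive from one master seed, so a
run is reproducible end to end. These sizes keep a complete train-and-
evaluate cycle around ten minutes on a single CPU core.

## Numerical and degenerate-input conventions

- Coordinates are (x, y) = (column, row), 0-based, pixel centers at
  integers; CSV floats carry 6 significant digits.
- Median of an even-sized pixel set is the midpoint of the two central
  values.
- Binarization tie at exactly the threshold goes to foreground.
- A blank composite plane normalizes against reference 1.0, so zero input
  yields zero output rather than an error.
- `jaccard` of two empty sets and `mean_patch_iou` with empty ground truth
  are undefined and raise; an Otsu threshold of a constant image falls back
  to 0 (nuclei filter) or to the constant itself (gating, so nothing is
  positive).
- Training aborts with a diagnostic if the loss goes non-finite.
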