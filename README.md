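# imcseg

Cell segmentation and single-cell quantification for imaging mass cytometry
(IMC), built around a patch-wise U-Net.

## The problem

An IMC acquisition of a tissue region yields ~40 registered single-channel
images of raw ion counts, one per metal-tagged antibody. Every downstream
analysis — phenotyping, neighborhood analysis, gating — stands on the first
step: assigning pixels to cells. Classic pipelines (pixel classifiers plus
watershed-style segmenters) are laborious and prone to inventing cells where
no nucleus exists. `imcseg` implements the deep-learning alternative: a
U-Net semantic segmentation of a two-plane membrane/nuclei composite,
followed by rule-based cleanup and per-cell quantification, plus the
evaluation metrics to judge the result both geometrically and biologically.

## What it computes

**Composite.** Selected membrane channels are summed into one plane and the
nuclei stain forms the other; both are median-filtered, Gaussian-smoothed,
gain-adjusted (nuclei ×2.5, membrane ×6.0 by default) and clipped to [0, 1].

**Segmentation.** The composite is tiled into 128×128 patches; a U-Net
(contracting blocks of paired 3×3 convolutions + ReLU with 2×2 max-pooling,
an expansive path with 2×2 up-convolutions and skip concatenations, 1×1
logistic output) predicts per-pixel cell probability

    p(x) = σ(f_θ(composite)(x)),

trained with per-pixel binary cross-entropy

    L(y, ŷ) = −(1/N) Σᵢ [ yᵢ ln ŷᵢ + (1−yᵢ) ln(1−ŷᵢ) ]

under Adam (batch 16, early stopping on validation loss). Probabilities are
binarized at 0.5. The network is implemented in NumPy — no deep-learning
framework required — with backprop verified against finite differences.

**Post-processing.** Connected components of the binary mask become cell
instances; then, in order: objects with no nuclei signal are eliminated,
1–2-pixel objects are removed, and enclosed holes are filled.

**Quantification.** Per cell: centroid, pixel count, and per-marker mean and
median intensity measured on the raw stack. Two CSVs are written
(`cells_mean.csv`, `cells_median.csv`); medians resist the hot pixels
typical of ion-count images.

**Metrics.** Per-cell IoU (Jaccard) against ground truth, mean over truth
cells and patches; percentage of *real cells* (objects whose mean nuclei
intensity reaches 10% of the nuclei grayscale range); and the
double-positive rate for mutually exclusive lineage pairs such as CD3/CD20 —
cells "expressing" both flag segmentation or gating errors.

A synthetic-scene generator (`imcseg.synthetic`) produces IMC-like stacks
with exact ground truth — nuclei disks, membrane rings, Poisson background,
hot pixels, optional anucleate contamination — so the full pipeline is
trainable and testable with no external data.

## Worked example

Simulate a scene, train a small network, segment, quantify, evaluate:

```bash
imcseg --seed 5 --out-dir out/sim simulate --n-scenes 1
imcseg --seed 5 --out-dir out/train train --n-scenes 12 --max-epochs 10
imcseg --seed 5 --out-dir out/seg segment \
    --stack out/sim/scene_000/stack.tiff \
    --names DNA,CD3,CD8,CD20,CD68,PanKeratin \
    --panel examples/panel.yaml --checkpoint out/train/unet.npz
imcseg --seed 5 --out-dir out/quant quantify \
    --mask out/seg/mask.tiff --stack out/sim/scene_000/stack.tiff \
    --names DNA,CD3,CD8,CD20,CD68,PanKeratin
imcseg --seed 5 --out-dir out/eval evaluate \
    --mask out/seg/mask.tiff --stack out/sim/scene_000/stack.tiff \
    --names DNA,CD3,CD8,CD20,CD68,PanKeratin \
    --panel examples/panel.yaml --truth out/sim/scene_000/truth.tiff
```

Output of the run above:

```
scene_000: 60 cells, 6 channels
trained 10 epochs, best val loss 0.0568 -> out/train/unet.npz
segmented 58 cells -> out/seg/mask.tiff
58 cells -> out/quant/cells_mean.csv, out/quant/cells_median.csv
n_cells	58
pct_real_cells	100.0000
mean_iou	0.810981
pct_double_positive_CD3_CD20	1.7241
pct_double_positive_PanKeratin_CD8	3.4483
```

Reading it: the generator placed 60 cells; this deliberately short training
run (10 epochs on 12 scenes) recovers 58 objects — two pairs of neighboring
cells merged into single components — every surviving object sits on nuclei
signal (100% real cells), and the whole-image mean per-cell IoU against the
ground-truth mask is 0.81. The merged pairs are exactly what the exclusive-
marker metric catches: one CD3+/CD20+ fusion among 58 cells = 1.72%. The
benchmark-scale training below (50 scenes, up to 25 epochs) pushes mean IoU
to ~0.95 and the double-positive rate to ~2.5% across 18 scenes.
`cells_mean.csv` holds one row per cell: `cell_id, centroid_x, centroid_y,
n_pixels`, then one column per marker with its mean intensity;
`cells_median.csv` is identical but with medians.

Every subcommand writes a `manifest.json` recording the resolved parameters
and seed, so any artifact can be regenerated from its manifest alone.

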