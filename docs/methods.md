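# Methods

## Problem and scores

The package quantifies UV-induced DNA damage in immunohistochemically
stained epidermis sections (CPD and 6-4PP photoproduct stains on human
skin, reconstructed skin models and porcine ear skin). Two per-sample
scalar scores are in play:

- **S_nuclei = N_dmg / N_all** — the fraction of damaged nuclei among all
  nuclei visible in the epidermis. This is the classical pathologist
  annotation: cheap per sample (a weak label) but noisy, particularly on
  slides with spatially heterogeneous damage, where two experts can
  disagree substantially.
- **S_area = A_dmg / A_epi** — the damaged-pixel area over the total
  epidermis-pixel area, derived from a 3-class segmentation mask
  (0 background/other, 1 healthy epidermis, 2 damaged epidermis). The
  damaged class is a subset of the epidermis, so A_epi counts damaged
  pixels too and the score is always in [0, 1]. A mask with no epidermis
  has no defined score; the package raises `UndefinedScoreError` rather
  than returning 0, so epidermis-detection failures surface explicitly.

Because both scores estimate the same underlying damage level, the
cross-score conversion used to fill the off-diagonal cells of the model
comparison is the identity: an area score is compared directly against a
nucleus score and vice versa.

## Estimators

**Segmentation model.** A U-Net that pools three times with base widths
16, 32 or 64 (channel progression w, 2w, 4w, bottleneck 8w; two
convolutions and two batch normalizations per block; nearest-neighbour
upsampling with skip concatenation; per-pixel 3-way softmax). Training
samples 256 px patches from 2x-downsampled images with random flips,
brightness in [0.75, 1.25] and rotations in [-15°, 15°]; the reference
recipe is 50 epochs x 100 steps x batch 32 under Adamax (lr 0.001,
beta1 0.9, beta2 0.999, eps 1e-7) with categorical cross-entropy, five
independent trainings per fold. Full-image inference slides a window over
the downsampled image (stride = half window, last window snapped to the
border), averages overlapping probability maps, takes the argmax (ties
toward the lower class index) and upsamples labels nearest-neighbour to
the original resolution. S_area is then an exact pixel tally on the
predicted mask.

**Regression model.** A VGG16-style backbone (13 convolutions, VGG
channel plan) on 4x-downsampled images, followed by concatenated global
max- and mean-pooling (1024 = 512 + 512 features at full width), dropout
(rate 0.5), a 128-unit ReLU layer, dropout and one sigmoid output neuron.
The loss is MSE on the sigmoid output (MAE available as a config option);
the optimizer is Adamax. Two deliberate departures from the classical
VGG16: batch normalization after every convolution, because the network
here trains from scratch on CPU rather than starting from ImageNet
weights, and a `width_scale` knob that shrinks all channel counts
proportionally for desk-scale experiments. ImageNet pretraining is not
reimplemented; `pretrained=True` requires a user-supplied checkpoint.

**Masked regression.** Identical to the regression model, but every input
is first multiplied by a binary epidermis mask predicted by a separately
trained U-Net (encoder widths 32/64/128/256, per-pixel binary
cross-entropy, Adamax lr 0.001, reference recipe 150 epochs x 50 batches
x batch 32 on 256 px patches of 2x-downsampled images, threshold 0.5).
Masking happens before downsampled-resolution training and prediction, so
the regressor sees epidermis pixels only.

All three networks are implemented in-package on numpy (`epiderm.nn`)
with explicit backward passes; gradients are verified against finite
differences in the test suite. Inputs are scaled to [-0.5, 0.5]. Weight
initialization is He-normal. Everything is deterministic given the
configuration seed on a single-threaded CPU run.

## Synthetic data generator

The generator emulates the stained fields of view the pipeline targets,
with exact ground truth. Geometry: an undulating epidermis band touching
the top image edge (thickness drawn from 45-70 µm, sinusoidal undulation
of 12 µm amplitude and 60 µm period at the acquisition resolution of
0.645 µm/px; defaults render 256x256 fields, a full-slide preset renders
1040x1384). Nuclei are filled ellipses of 4-8 µm diameter placed
uniformly inside the band at 0.008 nuclei/µm², a plausible keratinocyte
packing at this resolution.

Damage placement is the generator's single modelling idea: Gaussian-
filtered white noise thresholded at the quantile that makes the damaged
share of band pixels equal the target fraction exactly (up to pixel
quantization). The filter length scale is the heterogeneity knob —
sigma = 1 px + heterogeneity x (image side / 4) — so heterogeneity 0
yields fine-grained, spatially uniform damage and 1 yields a few large
patches. A nucleus is damaged iff its centre lies in the damaged region,
so the recorded S_nuclei and S_area are exact tallies and every class-2
pixel lies inside the band by construction. Damaged nuclei are rendered
dark red and the damaged region receives a diffuse red-brown chromogen
tint (alpha 0.35), mirroring how immunostain deposits extend beyond
nuclear outlines; this also makes region-level damage locally learnable.
A contrast knob compresses all colours toward the slide background,
reproducing the low-contrast regime where epidermis detection fails.
Dataset-level generation draws per-sample damage fractions from a mixture
covering [0, 1] (15% near zero, 70% Beta(1.5, 2), 15% near one) and
heterogeneity uniformly.

A descriptive `heterogeneity_index` turns any mask into a [0, 1] score:
the standard deviation of per-tile damage fractions (default 32 px tiles,
tiles weighted by their epidermis pixel count so band slivers at tile
borders do not dominate), rescaled by 0.5, the largest sd a [0, 1]-valued
quantity can attain.

What the generator does **not** emulate: stain physics (no Beer-Lambert
chromogen model), nucleus-instance ground truth beyond centre + flag,
slide artefacts (folds, bubbles, out-of-focus regions), scanner-to-scanner
colour variation, and the correlation structure of real annotation errors.
Passing the desk-scale recovery runs therefore shows that the estimators,
training loops and metrics are implemented correctly and can learn this
class of signal — not that they reach any particular accuracy on real
histology.

## Annotator model

Pathologist annotations of S_nuclei are simulated as truth + Gaussian
noise truncated to [0, 1], with sd = base (0.05) + coupling x
heterogeneity. The coupling default (0.14) is calibrated by bisection on
a Monte-Carlo estimate so that two independent annotators disagree with
MAE ~ 0.2 on fully heterogeneous samples. Reported interobserver
disagreement for pathologist pairs on such critical samples spans roughly
MAE 0.17-0.23; the default target 0.2 sits inside that range, and
`calibrate_coupling` accepts any target. A truncated Gaussian was chosen
over a Beta model because only a target MAE and spread are available to
calibrate against.

## Evaluation machinery

- MAE statistics use the population (not sample) standard deviation of
  absolute errors, reading "standard deviation of absolute errors"
  literally.
- Macro-IoU averages the per-class Jaccard index over exactly the three
  classes; a class absent from both masks scores 1.0. A small spurious
  prediction of an absent class therefore drags the macro average down —
  deliberately, as this mirrors how near-perfect predictions of fully
  damaged samples are scored.
- Stratified k-fold (default k = 10) groups samples by (staining, tissue,
  mask availability), shuffles within each stratum and deals round-robin
  with the dealing position carried across strata, so per-stratum counts
  and total fold sizes both differ by at most one.
- The agreement analysis is a paired nonparametric bootstrap: 1000
  replicates resample the n score pairs with replacement and recompute
  (MAE, sd of absolute errors). No multiple-testing correction is applied;
  distributions, not corrected p-values, are reported. The human-level
  comparison statistic is the fraction of paired draws in which the
  model-vs-annotator MAE lies below the annotator-vs-annotator MAE.

## Desk-scale problem sizes

The reference training recipes above target a full 804-sample dataset and
are impractical for a quick CPU run, so the package's own recovery
experiments (tests and `scripts/acceptance.py`) use scaled-down synthetic
runs chosen once as the smallest sizes at which learning is clearly
demonstrable: segmentation trains U-Net/16 on 60 of 72 synthetic 256 px
samples for 5 epochs x 20 steps x batch 8 at Adamax lr 0.01 (the higher
rate compensates for the ~50x shorter schedule); regression trains the
width-scale-0.25 backbone on 80 of 100 samples for 20 epochs x 20 steps x
batch 8 at lr 0.01. Held-out targets are macro-IoU >= 0.70 and
MAE[S_area] <= 0.10 for segmentation and MAE[S_nuclei] <= 0.15 for
regression (against a predict-the-mean baseline around 0.27). The width
ablation compares U-Net/16 and U-Net/64 across 3 seeds on an even smaller
128 px benchmark and asserts the wider model is not worse by more than
0.02 macro-IoU.

## Numerical choices and degenerate inputs

- Stitching averages probabilities, then argmaxes; ties break toward the
  lower class index. Averaging is smooth and window-order independent.
- Sliding-window edge handling snaps the last window to the border
  (overlap grows) instead of zero-padding, avoiding fabricated background.
  Images smaller than one window are reflect-padded and cropped back.
- Downsampling: bilinear anti-aliased for images, nearest for masks
  (label set preserved); output dims are ceil(input/factor), so the
  1040x1384 acquisition size maps to 260x346 at factor 4.
- Brightness augmentation is a multiplicative RGB factor clipped to
  [0, 255].
- 2x2 max-pooling replicate-pads odd spatial dims, so the VGG backbone
  accepts the 260x346 downsampled full-slide geometry.
- Undefined scores (no nuclei counted, no epidermis present or predicted)
  raise `UndefinedScoreError`; orchestration code records such samples as
  flagged failures.
- Mask files are 8-bit paletted PNGs (0 black, 1 green, 2 red); an
  RGB-encoded mask is translated through a configurable colour table, and
  unknown values or colours fail loudly naming the offending value.
- The manifest is a CSV with a YAML sidecar carrying resolution, image
  dims, palette and an exclusion list (default empty) for reproducing
  analyses that drop individual samples.

## Known limitations

- The in-package numpy networks are CPU-bound and single-threaded; the
  reference full-scale recipes (e.g. U-Net/64, 50x100x32) are expressed
  in configuration but are not practical to run here.
- The synthetic renderer's colour palette makes the three classes locally
  separable; real slides contain ambiguity (fading stain, partial-volume
  pixels) that the generator does not model, so absolute metric values on
  synthetic data overstate real-data performance by design.
- `deposit_statistics` expects the package's own manifest layout; pointing
  it at an arbitrary directory requires arranging `manifest.csv`,
  `images/` and `masks/` first.
- The regression model's dropout placement and fine-tuning depth had to be
  fixed by choice (dropout 0.5 at both head positions, backbone trained
  end-to-end), as did the regression loss (MSE).
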