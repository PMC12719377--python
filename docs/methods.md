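# Methods

## Problem setting

The package segments the three major intracranial tissues — white matter
(WM), grey matter (GM) and cerebrospinal fluid (CSF) — from co-registered
virtual monoenergetic CT images (VMIs) at 50, 70 and 120 keV. Each case is
a `SpectralStack` (three HU-valued volumes on one grid) plus a
`TissueLabelMap` with classes {0 background, 1 WM, 2 GM, 3 CSF}. The three
energies bracket the useful spectral range: low keV maximises grey/white
contrast at the price of noise, 70 keV resembles a conventional
polyenergetic image, and above ~120 keV attenuation changes become
negligible.

## Synthetic head-phantom cohort

No patient data ships with the package; a parametric phantom generator
(`spectralseg.phantom`) emulates the study conditions.

**Geometry.** Nested ellipsoids, outside-in: background, a CSF shell
(default 6 mm), a cortical GM ribbon (default 12 mm), the WM core, and a
CSF-filled ventricle (default semi-axes 18 x 12 x 10 mm). The head
semi-axes default to 75 x 85 x 55 mm on a 64 x 64 x 32 grid at
3 x 3 x 4 mm spacing, adult-head scale at a CT-typical slice thickness.
The GM/WM interface is perturbed radially by
`A * sin(f*phi + phi0) * cos(f*theta + theta0)` in spherical angle
(default amplitude 6 mm, frequency 6 cycles per revolution; phases drawn
per case) — a deliberately crude stand-in for cortical folding that
nevertheless creates the thin, high-curvature structures on which overlap
and surface-distance metrics are actually sensitive. Per-case realism
comes from jittering every geometric parameter by a uniform ±10%, which
gives cross-validation folds and jackknife resampling genuine inter-case
variance to act on. Geometries that collapse any class to zero voxels
raise a `DegenerateGeometryError` rather than silently producing a
three-class phantom.

**Spectral model.** Voxel values are the class's mean HU at that energy
plus white Gaussian noise, independent across energies. The default table
(HU):

| class | 50 keV | 70 keV | 120 keV |
|-------|-------:|-------:|--------:|
| CSF   | 7      | 9      | 10      |
| WM    | 31     | 29     | 28      |
| GM    | 44     | 38     | 34      |
| background | −1000 | −1000 | −1000 |

with noise sd 6 / 4 / 3 HU at 50 / 70 / 120 keV. The *trends* are the
modelled physics — GM−WM contrast strictly decreasing with keV (13 → 9 →
6 HU), noise strictly decreasing, CSF < WM < GM at every level — and the
constructor enforces them as invariants for any user-supplied table. The
absolute numbers are plausible brain-window values chosen once; they are
configuration, not claims. The phantom deliberately omits beam hardening,
partial-volume blur, skull/bone (only intracranial classes are segmented)
and any anatomical realism beyond the nesting; passing tests therefore
demonstrate that the pipeline's machinery works and that spectral trends
are exploitable, not that clinical accuracy transfers to patients.

## Input assembly

Models are 2-D with pseudo-3D context: a sample for axial slice z is the
`k = 3` consecutive planes z−1, z, z+1 per energy level, stacked as
channels, level-major (50, 70, 120), inferior-to-superior within a level.
At the volume ends missing planes are replaced by the nearest valid slice
(edge replication) rather than zero padding, which would inject an
artificial intensity step. `k` is interpreted as the *total* slice count
(centre ±1). Intensities are clipped to a (0, 100) HU brain window and
mapped affinely to [0, 1]; the window covers the CSF-to-GM range and is
configurable.

## Architectures

Two backbones (`spectralseg.architectures`), built on the package's own
numpy autodiff engine (`spectralseg.nn` — reverse-mode, 2-D conv /
transposed-conv / max-pool / instance-norm / PReLU / attention primitives,
Adam optimiser):

- **U-Net** — classic encoder-decoder, channel plan (24, 48, 96, 192)
  with a 288-wide bottleneck, two 3x3 conv + instance norm + PReLU stages
  per block, 2x2 max-pool down, 2x2 transposed-conv up, 1x1 output head,
  softmax over four classes: 3 545 542 trainable parameters (3.5 M).
- **U-Net++** — the same encoder with dense nested skip connections;
  node X(i,j) receives all earlier level-i nodes plus the upsampled
  X(i+1, j−1). Deep supervision is off: the last nested node is the sole
  output, which keeps fold-ensemble averaging well-defined. Channel plan
  (18, 36, 72, 144) with a 252 bottleneck, LeakyReLU activations:
  2 619 958 parameters (2.6 M).

The bottleneck widths (1.5x and 1.75x the deepest encoder width rather
than 2x) are the result of sizing the plans to the intended parameter
budgets; both plans are configurable per model.

**Spectral variants.** `baseline` and `aug` share one architecture
(3 input channels); they differ only in sampling. `fuse` and `gated` take
9 channels, split internally into three per-energy pathways of one 3x3
convolution + activation + normalisation each, concatenated (3x the first
encoder width) and fed to the backbone. Instance normalisation is used in
the pathways as everywhere else; batch normalisation is implemented and
selectable per block for fidelity experiments. `gated` adds one additive
attention gate between the last up-convolution (gating signal) and the
top skip connection: alpha = sigmoid(psi(relu(Wx x + Wg g))), output
alpha ⊙ skip. The gating signal is bilinearly resampled to the skip's
spatial size if needed, and clamping alpha to 1 provably reduces `gated`
to `fuse` (tested). For U-Net++ the gate acts on the concatenated bundle
of all level-0 predecessors of the final node.

Inputs whose spatial size is not a multiple of 2^(depth−1) are
reflect-padded to the next multiple and the output cropped back, so the
output grid always equals the input grid.

## Training

K-fold cross-validation (default K = 7) partitions the cases into equally
sized folds (sizes differ by at most one), deterministically from a seed;
the assignment is persisted so every variant trains on identical folds.
One model trains per held-out fold. Epoch sampling: `aug` enumerates every
(case, slice, energy) triple — three times the slice count; `baseline`
uses the designated 70 keV level only; `fuse`/`gated` pack all levels into
one sample per slice.

The loss is the class-masked multi-class Dice loss: per class c present in
the batch (any positive target pixel), `1 − (2Σp_c t_c + s)/(Σp_c + Σt_c
+ s)`, averaged over present classes only. Absent classes contribute
exactly zero gradient — without this, slice batches lacking e.g. CSF pull
that class toward never being predicted. Presence is decided per batch;
background counts as a class (C = 4) under the same masking; the smoothing
term is s = 1e−5 in numerator and denominator so a perfect prediction
scores ~0.

Optimisation is Adam at learning rate 1e−3, batch size 8, 100 epochs by
default — the optimiser family and schedule are otherwise unconstrained
choices exposed in `TrainConfig` (no early stopping, no LR schedule).
Everything is seeded: model initialisation derives from (config seed, fold
index), the epoch shuffle from the model seed, so loss trajectories are
bit-reproducible.

## Inference and ensembling

Whole volumes are predicted slice-by-slice (batched), reassembled in
order. `baseline`/`aug` models are evaluated on the 70 keV volume;
`fuse`/`gated` consume all three. The final segmentation is the voxel-wise
argmax of the arithmetic mean of the K fold models' post-softmax
probability volumes — probabilities, not logits, are averaged, matching
the plain reading of "averaging the outputs" (configurable in principle
since a single model's probabilities pass through unchanged). The mean is
accumulated in extended precision so it is exactly invariant to the order
the fold models are listed in. Argmax ties break toward the lowest class
index, a fixed rule chosen for reproducibility. No post-processing
(largest-component filtering, hole filling) is applied.

## Evaluation

Per case and tissue class (background excluded):

- **DSC** = 2|A∩B|/(|A|+|B|); defined as 1 for two empty masks.
- **HD95**: border voxels are mask voxels with ≥1 face-adjacent
  (6-connected) non-mask neighbour; both directed nearest-neighbour
  distance sets are computed in mm (KD-tree), pooled, and the 95th
  percentile taken with linear interpolation between order statistics.
  The pooled-percentile convention makes the metric symmetric. An empty
  mask makes the metric undefined: it is recorded as missing, never 0.
- **AVD%** = (V_GT − V_M)/V_GT · 100, signed (negative = overestimation);
  volumes are voxel counts x voxel volume in mL. Absolute AVD is averaged
  per class and across classes for the single-number volumetric error.

Uncertainty: delete-one jackknife — n leave-one-out replicate means, the
jackknife standard error, and a normal-approximation interval mean ±
z(0.975)·SE; requires n ≥ 3. Model comparison: Welch's t-test
(Satterthwaite degrees of freedom, two-sided, via scipy) on per-case DSC,
Bonferroni-corrected by x7 and capped at 1. Bland–Altman points plot
signed AVD against the mean of the two volume estimates.

## Verification strategy

Every nontrivial numerical path is checked against an independent oracle:
all autodiff ops against central finite differences (float64); the masked
loss against a loop-based direct summation on random batches including
absent classes, plus an exact zero-gradient check; HD95 against an
all-pairs brute-force computation on random masks; Welch and jackknife
against hand-written textbook formulas; the phantom against analytic
ellipsoid volumes. The scaled-down end-to-end check trains a narrow
(6, 12, 24) 3-fold U-Net++ `aug` ensemble for 10 epochs on 8 of 10
phantom cases and requires held-out DSC ≥ 0.70 for WM, GM and CSF — the
problem sizes were chosen so the whole suite runs on a single CPU desk
machine; the full-scale configuration differs only in config values.

## Known limitations

- The phantom's tissues are homogeneous with white noise; there is no
  beam hardening, partial-volume mixing, pathology or skull, so absolute
  metric values on phantoms overstate what patient data would yield.
- The networks are 2-D with a 3-slice context window; no full-3D
  convolutions.
- The numpy engine is single-threaded BLAS-bound; it is sized for
  desk-scale experiments, not clinical throughput.
- Batch-norm pathways exist for fidelity experiments but the default (and
  tested) configuration is instance norm everywhere.
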