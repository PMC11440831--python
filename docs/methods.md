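# Methods

`bodycomp` re-implements an automatic pipeline for CT body-composition
analysis: select the axial slice at the third lumbar vertebra (L3) from an
abdominal CT volume, segment that slice into skeletal muscle (SM), visceral
adipose tissue (VAT) and subcutaneous adipose tissue (SAT), and derive the
sarcopenia metrics used in oncology (SMD, SMI, SMG, LBM).  Because no
clinical data ships with the package, a synthetic abdominal phantom
generator provides volumes with exactly known ground truth; the whole
system trains and validates on phantoms.

## The two-stage model

**L3 selection as 2-D segmentation.**  The 3-D problem is reduced to 2-D:
voxels outside a whole-body mask are zeroed, the volume is collapsed along
the anteroposterior axis by a maximum-intensity projection into a coronal
image (rows = craniocaudal position, columns = left-right), rows are
rescaled to a fixed millimetre pitch and padded to a fixed grid.  The
annotated L3 position becomes a horizontal band extended to 1 cm thickness
(to soften the extreme class imbalance of a 1-pixel line), and a U-net is
trained with dice loss to segment that band.  At test time the 2-class
probability map is averaged across columns into a 1-D craniocaudal signal,
smoothed with a Gaussian kernel, and the global maximum among local maxima
is taken as the L3 row; the projection's provenance (crop offset, row
pitch, padding) converts the row back to an original slice index.

**Body composition as 5-class segmentation.**  A second U-net labels each
pixel of the L3 axial slice as background, other body tissue, SM, VAT or
SAT.  Predictions are post-filtered with the global Hounsfield window: any
pixel with HU above 150 or below −500 is forced to background, which
removes bone, metal and air regardless of the network's opinion.  An
optional strict mode additionally applies the manual-segmentation windows
(muscle −29..150 HU, fat −500..−30 HU) per class; it is off by default so
the default pipeline matches the published post-processing exactly.

**Sarcopenia metrics.**  From the segmented slice and the pixel area:
tissue areas in cm²; SMD = mean HU of muscle pixels within [−29, 150];
SMI = muscle area / height² (cm²/m²); LBM = 0.3 × muscle area + 6.06 (kg).
The source text defines SMG as "muscle area × SMD" but prints units of
HU·cm²/m², which imply SMI × SMD; the package defaults to SMI × SMD and
offers `smg_mode="area"` for the literal reading.  This discrepancy is
surfaced, not resolved.

## Architecture and training

Both networks are a standard U-net: four encoder/decoder levels, two 3×3
convolutions + ReLU per level, 2×2 max pooling, nearest-neighbour
upsampling with skip concatenation, and a 1×1 softmax classifier.  Filters
start at 64 (L3 task) or 32 (body composition) and double per level.
Inputs are 1088×512 (L3) and 512×512 (body) in the full-scale profile.
Training uses soft dice loss (smoothing constant 1.0, per-sample sums,
averaged over the non-background classes), Adam at learning rate 1e-4 with
batch size 8, up to 100 epochs with early stopping on the validation loss
(patience 10, min-delta 1e-4, both unstated in the source and chosen here),
and the checkpoint returned is the epoch with the best validation DICE.
The implementation is pure numpy with analytic backpropagation (verified by
finite differences); convolutions are computed as nine shifted BLAS
matmuls, and all randomness (initialization, shuffling, jitter) flows from
explicit seeds, so runs are bit-reproducible.

Two numerical choices depart from an earlier internal default and are worth
stating.  First, network inputs are HU windowed to [−200, 250] and scaled
to [0, 1] — a soft-tissue display window.  A symmetric [−1000, 1000] window
compresses the muscle/fat contrast into ~7 % of the input range and
measurably slows training at the short desk-scale budgets.  Second, the
final 1×1 classifier is zero-initialized (training starts from uniform
class probabilities so every class receives gradient) and gradients are
clipped to unit global norm: with a foreground band occupying ~2 % of the
image, occasional gradient spikes otherwise poison Adam's second-moment
estimates and can collapse the run into the all-background minimum, from
which the softmax-dice gradient cannot recover.  For the same reason the
binary L3 loss keeps only the band class in the loss: including the
background class creates an all-background attractor at loss ≈ 0.5.
A related numerical detail: gradient values below 1e-20 (1e-16 for
parameter gradients) are flushed to zero — once the network is confident,
the dice gradient chain otherwise fills with float32 subnormals, which
stall CPU arithmetic without affecting the optimization.

**Augmentation.**  Training enlarges the dataset with geometrically
transformed copies (rotation, scaling, translation; identical transform
applied to image and target) and, for axial slices, artificial arm sections:
soft-tissue-HU ellipses painted lateral to the thresholded body mask with
random size, position and orientation.  Arms are deliberately labelled
background — the pipeline's goal is to exclude them from body-composition
measurements — so the network learns to suppress them.

## The synthetic phantom

Geometry is stylized — ellipses and cylinders — because the pipeline's
operators need contrast, topology and HU statistics, not anatomy: a trunk
ellipse with an outer SAT shell (default 18 mm) and a muscle wall (10 mm);
paraspinal muscle bodies; a VAT interior containing a soft-tissue "organ"
whose HU (50 ± 10) deliberately overlaps muscle so the segmentation task
cannot be solved by thresholding alone; a vertebral column of bone
cylinders (35 mm bodies, 8 mm disc gaps, both jittered) whose third body
from the pelvis is L3; two lungs in the cranial third; a pelvic girdle
(two wings joined by a sacral bar) caudally; optional arms lateral to the
trunk (detached, labelled background) and an optional intravertebral
implant at 1500 ± 100 HU emulating cementoplasty.  Tissue HU values are
drawn from ±3σ-truncated normals (air −1000, lung −800±50, SAT −105±20,
VAT −90±20, muscle 45±15, bone 400±100) plus global Gaussian scanner noise
(default σ = 10 HU), so with zero noise every labelled voxel provably
respects the manual-threshold windows.  Cohort generation jitters body
scale (±15 %), vertebral height (28–42 mm), column origin, SAT/muscle
thickness, patient height (1.50–1.90 m) and slice thickness
({1, 2.5, 5} mm), and assigns arms to 20 % and implants to 10 % of
phantoms.

What the phantom does **not** emulate: organ texture, contrast phases,
partial-volume effects, anatomical shape variation, pathology (ascites,
carcinomatosis), or beam-hardening artifacts.  Passing the phantom studies
therefore demonstrates that the pipeline's machinery — preprocessing,
coordinate bookkeeping, training, post-processing, metrics — is correct
and that the tasks are learnable at the stated noise and diversity; it
does not certify clinical performance.

## Reduced-scale ("desk") study conditions

The full-scale profiles mirror the clinical setup but are not trainable in
minutes on one CPU, so the end-to-end studies run at a reduced scale whose
sizes are fixed as part of the package's study conditions:

- phantom volumes 96×96 in-plane at 2.25 mm, 432 mm craniocaudal extent,
  slice thickness drawn from {1, 2.5, 5} mm;
- coronal grid 3 mm/row with 2× column max-pooling (4.5 mm/col),
  standardized to 144×48 (the L3 band is a per-row structure, so coarse
  columns lose nothing the desk task needs);
- U-nets of depth 3 with 16 base filters; 15 epochs of Adam 1e-4, batch 8;
- cohorts of 200 phantoms: 160 train / 40 held-out test, with the last 16
  training phantoms used only as the checkpoint/early-stop monitor;
- training sets enlarged by augmentation (×3 for L3 detection, ×2 with arm
  insertion for body composition);
- peak smoothing σ scaled to ≈1 cm of craniocaudal distance.

At 3 mm slices the slice-index quantization alone contributes up to 1.5 mm
of |error| to the L3 measurement, which bounds how small the desk-scale MAE
can be.

## Numerical and degenerate-input conventions

- 0-based slice indices; z = index × spacing, caudal → cranial; row↔slice
  conversions round half-up (toward cranial) and are exercised for exact
  round-trip identity over spacings {1, 2.5, 5} mm.
- Body mask: threshold −200 HU, 5 mm closing, largest connected component,
  per-slice hole filling (lungs and bowel gas belong to the body), 5 mm
  dilation.  All-air volumes raise a degenerate-input error.
- Pre-crop: lung centroid from the largest air component inside the eroded
  body mask; pelvic centroid from the skeleton of the largest caudal-half
  bone structure (isolating the pelvic girdle from the column before
  skeletonizing); crop only when the centroids are > 20 cm apart, with a
  20 mm margin.  A missing lung or pelvis falls back to no crop with a
  warning.
- Empty∩empty DICE is 1 (perfect agreement on absence); argmax ties break
  toward the lowest class code; signal-peak ties toward the most caudal row.
- MAPE is undefined when any truth value is zero and R² when the truth has
  zero variance; cohort evaluation reports such quantities as undefined
  with their coverage rather than guessing.

## Known limitations

- The numpy networks are CPU-bound; the full-scale profiles (depth 4,
  base 64, 1088×512) are architecture-complete and shape-tested but not
  trained in the test suite.
- The phantom's stylized geometry makes the desk segmentation task easier
  than clinical slices in shape (smooth boundaries) and harder in one
  respect (the organ's HU exactly overlaps muscle); DICE values on
  phantoms are therefore not comparable organ-for-organ with clinical
  reports, only usable as analog bounds.
- DICOM support is import-only and covers plain CT series with rescale
  tags; enhanced multi-frame DICOM is out of scope.
- Patient height is never read from DICOM (unreliable in practice); it is
  an explicit input wherever SMI/SMG are requested.
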