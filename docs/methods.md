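# Methods

## Problem and model

`hfsnet` implements a hierarchical, coarse-to-fine strategy for detecting
and segmenting hepatocellular carcinoma (HCC) in three-phase dynamic CT
(non-contrast, arterial, portal-venous).  The method divides the problem by
lesion size because the imaging evidence differs by size: small HCCs are
best found by combining all three phases (arterial hyperenhancement and
portal-venous washout are the discriminative signal), while large HCCs have
clear edges in the portal-venous phase alone.

The pipeline cascades five sub-models in three stages:

| stage | model     | input                | architecture  | loss         |
|-------|-----------|----------------------|---------------|--------------|
| I     | `f_liver` | portal-venous slices | 2D DenseU-Net | ce + dice    |
| I     | `f_size`  | 3-channel dynamic    | 2D DenseU-Net | focal + dice |
| II    | `f_large` | portal-venous slices | 2D U-Net      | ce           |
| II    | `f_small` | 3-channel dynamic    | 2D DenseU-Net | focal + dice |
| III   | `f_3d`    | 5-channel fusion     | 3D U-Net      | focal + dice |

Stage I produces a liver probability map and a coarse tumor map used only
for size estimation.  Stage II labels the coarse map's per-slice connected
components (8-connectivity) and measures each component's longest axis —
the maximum pairwise distance between pixel centers.  Components with axis
≤ m = 30 px go to the small branch, components with axis > 30 px to the
large branch; at 1.4 mm/px the demarcation is 4.2 cm.  A slice enters a
branch's input set when it holds at least one component of that branch, so
a slice containing both a small and a large lesion is fed to both branches
and the fusion stage reconciles them.  Stage III stacks the normalized
portal-venous image with the four sub-model probability maps (fixed channel
order: image, liver, size, large, small; the order is hashed into the run
config so silent reordering is detectable) and a 3D U-Net, run on
overlapping Z patches blended with triangular weights, produces the final
probability volume.  The final mask is the 0.5-threshold binarization,
intersected with the predicted liver (lesions are intrahepatic by problem
definition; gating is a config switch), with connected components below
3 voxels removed as speckle.

"2D mode" stops after Stage II and takes the union of the branch outputs;
it exists to quantify what the volumetric fusion stage adds.

## Architectures and the numpy backend

The networks are compact, configurable U-Nets: `depth` resolution levels
(factor-2 in-plane pooling; the 3D variant pools only in-plane so shallow
Z patches survive), `base_width` channels at the top level doubling per
level, nearest-neighbour upsampling with skip concatenation, softmax head.
The head bias is initialized so the network starts predicting foreground
with probability ~0.02 — the focal-loss prior trick — which stops the
overwhelming early background gradient from stalling small-lesion
learning; it markedly shortens the warm-up of the lesion models under both
focal and plain cross-entropy training.
The DenseU-Net replaces each plain two-convolution block with a dense
block: two 3×3 layers whose outputs are concatenated onto their inputs
(tightly connected paths), followed by a 1×1 transition; `growth_rate = 0`
degenerates exactly to the plain block, which is exercised as a test
property.  Exact layer counts of the original clinical models are not
published, so the canonical published forms of U-Net/DenseU-Net are used
with size as configuration.

Models train and run on a small reverse-mode automatic-differentiation
backend (`hfsnet.nn`) written on numpy: same-padding stride-1 convolutions
via sliding-window views and `tensordot`, factor pooling, ReLU, stable
softmax, elementwise ops and reductions, and Adam.  Gradients are verified
against central differences in the test suite.  The default "tiny" profile
(depth 3, base width 8, 64×64 slices) trains each sub-model in well under a
minute on one CPU; the same code scales to 256×256 by configuration.

## Losses

Cross entropy, soft dice (`1 − (2·Σpt + s)/(Σp + Σt + s)`, smoothing
s = 1.0), focal loss (`−w_c (1−p_t)^γ log p_t`, default γ = 2, the original
formulation's value), and median-frequency-balance weights
(`median(freq)/freq_c`, applicable to either cross entropy or focal loss —
the published description is ambiguous on which, so the weights compose
with both).  Compound losses are plain unit-weight sums ("ce+dice",
"focal+dice"), matching how they are conventionally written; probabilities
are clamped to `[1e-7, 1−1e-7]` before logarithms.  `focal(γ=0) ≡ cross
entropy` is asserted to 1e-6 as an identity test.

## Training protocol

Cases are split 5:2:3 (train/validation/test) by a seeded case-level
shuffle, rounding remainders into the training set.  Each sub-model trains
with Adam (lr 3e-3) on sampled slice batches — 70% positive slices for its
task, 30% background — with horizontal/vertical flip augmentation, early
stopping on validation Dice, and best-validation weight selection.  The
Stage-II branches pick their training slices by ground-truth routing (a
slice is a small-branch positive when it contains a lesion with axis
≤ 30 px) and are validated on those routed slices only.  `f_3d` trains on
Z patches of the 5-channel stacks produced by the already-trained Stage
I/II models.  `f_size` and `f_small` share a strategy but are trained
independently (a shared-weights switch exists in the config) because the
pipeline treats them as separate functions.  Everything is deterministic
given the seed.

## Evaluation protocol

Segmentation: Dice per case (unweighted mean of case-level Dice) and Dice
global (pooled voxel counts); Jaccard is reported as a secondary output;
Dice of two empty masks is defined as 1 (affects tumor-free slices only).
Detection: within each slice, predicted components and reference instances
are matched greedily by descending pairwise Dice, one-to-one, counting only
pairs with Dice > θ = 0.2 ("significant but not exact overlap"); matched
references are TPs, unmatched references FNs, unmatched predictions FPs.
Sensitivity/precision/F1 are reported at four granularities: per tumor
volume (all per-slice instances pooled), per tumor cut (per-case rates
averaged), per slice (a tumor-bearing slice counts when ≥ 1 of its tumors
is detected; precision over all predicted-positive slices, so false alarms
on tumor-free slices count — a config switch restricts to tumor-bearing
slices), and per patient (a case counts when ≥ 1 tumor is detected).
MTD MAE is the mean absolute error of the per-case maximum tumor diameter,
the largest per-slice longest axis over all instances converted to cm.
Reports are stratified by reference MTD (size bins <2, 2–3, 3–5, >5 cm,
left-closed boundaries, so an MTD of exactly 2.0 cm falls in 2–3 cm) and by
tumor count (1, >1); empty strata are flagged with NaN metrics, not errors.
Every metric is cross-checked against independent brute-force
implementations (exhaustive voxel counting, flood-fill labeling, O(n²)
matching) to 1e-9 on random volumes.

## Synthetic phantoms

The generator emulates the statistical structure of a clinical HCC cohort
so the pipeline is trainable and testable without patient data:

* **Geometry** — an ellipsoidal liver; lesions are spheroids whose longest
  axis lies in-plane with a controlled maximum diameter (major semi-axis
  grown by a quarter voxel to offset tip quantization; voxelization error
  is verified ≤ 1 in-plane voxel).  The z semi-axis is kept shorter than
  the in-plane radius so the 3D maximum diameter equals the controlled
  in-plane one.  An optional shrink-only radial perturbation roughens the
  surface; it is off by default because diameter control is the ground
  truth the routing tests rely on.  Placement is rejection-sampled and
  verified voxel-exactly: every lesion voxel lies inside the liver and
  lesions do not touch.
* **Size mixture** — lesion diameters are drawn from the cohort's bin
  fractions 15.6% / 22.4% / 29.9% / 32.1% for <2, 2–3, 3–5, >5 cm,
  uniform within bin; 84% of cases carry a single tumor, the rest 2+ with
  a geometric tail.  Multi-tumor draws are rejection-sampled against a
  packing budget (total lesion sphere volume ≤ 40% of liver volume) so
  planned cases are placeable; the budget only binds on the tiny grid.
* **Intensity** — piecewise-constant HU-like compartment means per phase
  (liver 55/70/110, lesion 45/110/70 across non-contrast/arterial/
  portal-venous, soft-tissue background 0), Gaussian partial-volume
  smoothing (σ = 0.3/0.6/0.6 voxels) and additive Gaussian noise
  (σ = 10 HU).  The clinical cohort's intensity statistics are not
  published, so these defaults are chosen for radiological plausibility —
  arterial hyperenhancement and portal-venous hypodensity hold by
  construction — not fidelity to a scanner.
* **Profiles** — `full`: 64×256×256 voxels at (2.5, 1.4, 1.4) mm;
  `tiny`: 32×64×64 at the same spacing, the default for CPU-scale
  training and tests.  Phase volumes are generated pre-aligned (the
  clinical preprocessing aligned phases before modeling); small Z
  misalignments can be introduced through the I/O layer for testing the
  aligner.

What the phantoms do **not** model: lesion-shape irregularity beyond the
optional perturbation, vessels, breathing artifacts, inter-phase in-plane
motion, other lesion etiologies, scanner-specific noise texture.  Passing
the recovery study therefore shows the pipeline's machinery — routing,
branch specialization, fusion, metrics — is implemented correctly and can
learn phase-contrast structure; it says nothing about clinical accuracy on
real CT.

## Preprocessing

In-plane resampling to 1.4 mm/px (linear for intensities, nearest for
labels; physical extent preserved to one voxel), center crop/pad to
256×256, then clipping to a narrow soft-tissue window (W200/C50, i.e.
[−50, 150] HU — the clinically standard range for liver parenchyma
reading) and scaling that fixed window to [0, 1].  The window is fixed
rather than per-volume min-max because CT is calibrated in HU: a
data-dependent rescale maps the same tissue to different values depending
on what else is in the volume — a lesion-free liver would be stretched to
lesion-like brightness in the arterial phase, which measurably induced
false positives on clean anatomy before the change.  The clinical
description states neither the HU window nor the interpolation scheme;
both are explicit, config-recorded choices here.  Phase alignment matches slices by nearest
physical Z coordinate against the portal-venous grid restricted to the
common Z range, with tolerance half the slice spacing; no in-plane
registration is attempted.  An empty Z overlap raises an error, mirroring
the exclusion of unalignable studies from the cohort.

## Numerical and design choices

* Binarization threshold 0.5 for all probability maps; minimum component
  3 voxels (2D routing: 3 pixels); 8-connectivity in 2D, 26 in 3D.
* The routing tie at exactly 30 px goes to the small branch (the textual
  rule "less than or equal to m" is taken over a figure caption that says
  "over 30 pixels", which describes the complement loosely).
* Fusion consumes probabilities rather than binarized maps (richer
  evidence for the 3D net); a config switch provides the binary variant.
* Greedy best-Dice one-to-one matching is used for detection because the
  matcher is otherwise unspecified; ties break deterministically by
  instance id.
* Degenerate inputs: empty masks give Dice 1 against empty references and
  sensitivity 0 against non-empty ones; empty strata and denominators
  yield NaN, never exceptions; an empty per-slice component set yields an
  empty routing plan.

## Desk-scale study sizes

The recovery study and the acceptance script use 40 tiny-profile cases
(5:2:3 split → 20/8/12) and 12 steps of batch 6 per epoch, with a
per-sub-model epoch budget (4 for `f_liver`, 6 for `f_size`/`f_small`,
12 for `f_large` and `f_3d`): the prior-initialized focal/dice 2D learners
converge within a few epochs; the plain-cross-entropy large branch needs
most of its schedule for the class-imbalance breakthrough, and the fusion
model uses the full schedule — on a task where the 2D branches are already
near ceiling, an under-trained fusion stage is the one thing that can make
the 3D pipeline worse than the 2D one.  Whole-volume models are validated on a stride-2 slice
subsample, branch models on their routed slices.  These sizes are the
package's desk-scale defaults: every sub-model reliably exceeds 0.5
validation Dice and the full pipeline's held-out Dice global clears 0.5
with margin, while a full run stays in the minutes range on one CPU.

## Known limitations

The numpy backend is CPU-bound and sized for desk-scale experiments, not
clinical volumes at full resolution in bulk.  The phantom study cannot
validate clinical performance claims (the clinical cohort is private); the
reported desk-scale numbers characterize the implementation, not HCC
detection in patients.  R2U-Net, Hyper-DenseU-Net and Single Dense Path
U-Net — alternative architectures explored only in the original ablation —
are out of scope, as are surface-distance metrics, deformable
registration, and post-treatment/extrahepatic disease.
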