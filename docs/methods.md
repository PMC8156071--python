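# Methods

This note documents the models and procedures implemented in
`lymphopatch`, their assumptions and defaults, and the choices made where
the design was genuinely open.

## Tiling of annotated regions

An annotation is a polygon in pixel coordinates over an RGB image with a
known physical scale (µm/px). The patch side in pixels is
`round(patch_size_um / um_per_px)`, rounding half away from zero, so the
canonical 100 µm patch at 100/395 µm/px is exactly 395 px. The tile grid
is axis-aligned, anchored at the polygon bounding-box top-left (an
explicit, configurable convention — annotation tools do not standardize
the anchor), with stride equal to the side, so tiles never overlap.

A tile is kept iff its four corners and its center are covered by the
polygon (boundary-inclusive) and the full square lies inside the image.
The corner+center test is a fast approximation to full containment; the
test suite validates it against full rasterized-mask containment on
squares and circle polygons. Tiles straddling the annotation or image
border are dropped — the annotation protocol deliberately avoids tissue
edges, and partially filled tiles would over-represent them. Coordinates
are 0-based, x right / y down; a tile occupies the half-open square
`[x, x+side) × [y, y+side)`. Cases yielding fewer than 10 patches are
flagged (strictly fewer), mirroring the minimum-representation rule used
when curating patch cohorts.

## Patient-level splitting

Cases are split 60/20/20 into train/validation/test. Within each stratum
(class by default; stratification can be disabled) the case ids are
sorted, shuffled with the seed, and apportioned by the largest-remainder
rule, which guarantees realized counts within one case of the exact
quota and is deterministic. All patches inherit their case's subset;
`assert_single_subset` re-derives, per case, the set of subsets its
patches occupy and reports any case spanning more than one — the trainer
calls it and refuses to fit on a leaky split.

## The classifier family

The classifier is a small channels-last CNN built from a 3×3 convolution
stem followed by `depth` blocks of (3×3 convolution → ReLU → 2×2 max
pool), global average pooling, and a linear softmax head. Compound
scaling derives each family member φ from the baseline:
`depth = round(2·1.2^φ)`, `width = round(8·1.1^φ)` channels,
`resolution = round(32·1.15^φ)` px (coefficients configurable; parameter
count strictly increases with φ). The φ=0 baseline — depth 2, width 8,
resolution 32 — is sized so that a full training run takes tens of
seconds on one CPU core.

The network and its optimizer (Adam, default moment coefficients β₁=0.9,
β₂=0.999) are implemented directly in NumPy with explicit
forward/backward passes (im2col convolutions). This buys three properties
the pipeline needs: bit-exact determinism for a fixed seed on a single
thread, batch-size-invariant inference, and exact input gradients for
saliency. Images are bilinearly resized to the member's resolution and
affinely mapped to ≈[−0.5, 0.5] before the network.

Training protocol:

- **Learning-rate screening**: each candidate rate trains for a fixed
  number of epochs (50 by convention; configurable) from the *same*
  initialization; the rate with the highest validation accuracy wins,
  exact ties to the smaller rate. The default rate 3e-3 suits the φ=0
  member on the synthetic cohorts; rates appropriate for billion-weight
  members are orders of magnitude smaller, which is why the sweep exists.
- **Checkpointing / stopping**: per-epoch training accuracy is the
  running batch average; validation accuracy is computed on the full set
  after each epoch. The weights of the best-validation-accuracy epoch are
  restored at the end. "Train until no further gain" is operationalized
  as early stopping with a patience of 10 epochs (visual stopping is not
  reproducible).
- **Member selection**: best validation accuracy; candidates within 0.25
  percentage points are re-compared by validation balanced accuracy, and
  remaining ties go to the smaller φ (cheaper model).
- **Batch size**: validated to be a power of two (the convention when
  sizing batches to accelerator memory); 32 by default.

Initialization is He-normal from the seed; no pretraining (a flagged
open question in the source protocol — random init is the reproducible
default here).

## Quality control and case-level evaluation

Evaluation runs on per-patch probability tables (`p_<class>` columns).

1. **Class aggregation.** Training uses the five-way vocabulary (SLL/CLL,
   DLBCL, LN lung, LN colon, LN pancreas) because organ-specific control
   labels are available and may help the classifier; evaluation pools the
   three controls into "tumor-free reference LN" by *summing their
   probabilities before* argmax and PQC. Rationale: a patch the model
   confidently calls "some tumor-free organ" should pass quality control
   even if the organ identity is split three ways. The alternative
   (argmax first, then map) is available via `patch_level_eval` on
   identity-mapped records.
2. **PQC.** A patch is discarded iff its maximum aggregated probability
   is strictly less than the threshold. The rejected fraction is reported
   as a percentage of all patches.
3. **Majority vote + CQC.** A case takes the modal argmax class of its
   surviving patches; modal ties break by higher summed probability, then
   by class order. The vote fraction is over PQC survivors (default):
   PQC-rejected patches were declared uninformative, so they do not
   dilute the vote; `cqc_denominator="all"` preserves the alternative. A
   case is UNCLASSIFIED iff no patch survived or the fraction is strictly
   below the CQC threshold. Zero-survivor cases count toward the CQC
   rejection percentage (the PQC column is patch-denominated).
4. **BACC.** Balanced accuracy is the unweighted mean of per-class
   recalls over classes that have at least one *classified* true item;
   classes absent after abstention are dropped from the mean with a
   warning rather than contributing zero recall. UNCLASSIFIED cases are
   excluded from the confusion matrix. Patch-level and case-level
   evaluation share this code path.

The default threshold grid is {0.5, …, 0.9} × {0.5, …, 0.9}, reported as
BACC %, PQC-rejected % and CQC-rejected % per cell (percentages to two
decimals in the wide export). The whole chain is cross-checked in the
test suite against an independently written nested-loop oracle, cell by
cell, on seeded fixtures.

## SmoothGrad

For a target class, the gradient of the *pre-softmax* score w.r.t. the
input is averaged over `n_samples` Gaussian-perturbed copies of the patch
(std = `noise_fraction ×` the patch's intensity range; defaults 0.005 and
50). The absolute averaged gradient is collapsed across color channels by
a per-pixel maximum, then min–max normalized to [0, 1): the denominator
is scaled by (1 + 2⁻²³) so the supremum is strictly below 1, and an
all-constant gradient field maps to all zeros. The logit is used because
softmax gradients saturate at confident predictions and any positive
scaling of the score cancels in the normalization (a tested invariance).
The per-pixel-max-after-averaging order is the default; max-per-sample-
before-averaging is available behind `channel_collapse` since the
upstream adaptation's exact order is not documented. Zero noise
short-circuits to a single vanilla gradient evaluation, which is the
exact limit of the average.

## Synthetic data

The generator emulates the three morphological contrasts the classifier
must exploit, not histology itself:

- **SLL/CLL**: dense small nuclei (7 ± 0.8 µm, 55 per 100×100 µm, nearly
  round).
- **DLBCL**: sparse large pleomorphic nuclei (16 ± 3 µm, 18 per
  100×100 µm, eccentricity up to 0.7).
- **Reference LNs**: intermediate nuclei; the lung variant adds
  near-black anthracosis pigment clumps, the colon/pancreas variants add
  pale sinus ellipses instead.

Nuclei are Gaussian-jittered filled ellipses on an H&E-like palette with
additive Gaussian noise — the simplest texture family that yields the
required class ordering (DLBCL nucleus area > SLL/CLL nucleus area,
verified by connected-component labeling) and ≥95 % separability by a
plain mean-nucleus-area threshold. All densities and sizes are artifact
choices; no quantitative morphometry was available to calibrate them.
Cohort cases are grid-aligned staircase polygons sized to realize an
exact per-case patch count drawn from the configured range.

What the renders do **not** contain: staining variability, focus/scanner
artifacts, nuclear chromatin texture, cell crowding/overlap statistics,
stromal architecture. Passing tests on this substrate therefore
demonstrates the correctness of the pipeline's mechanics (tiling, splits,
training dynamics, QC arithmetic, saliency plumbing) and the *learnability
ordering* of morphology-scale features — not clinical performance.
Published clinical headline numbers depend on the original patient cohort
and a full-scale trained network and are out of scope here.

Probability fixtures are generated independently of any model: each patch
is correct with the configured probability; its assigned class's Dirichlet
concentration is boosted (more for correct patches when
`confidence_correct_boost > 1`), and the maximum component is swapped into
the assigned slot so target accuracy is met exactly in expectation while
confidence correlates with correctness — the two knobs the QC tests need
to vary independently.

## Problem sizes and numerical choices

Desk-scale study conditions used by the tests and the acceptance script:
3 classes (SLL/CLL, DLBCL, LN lung), 30 cases/class, 20–40 patches/case,
µm/px = 100/32 (so a 100 µm patch is 32 px, the φ=0 input resolution),
≈2 700 patches total; training 14 epochs, Adam 3e-3, batch 32. A full
training run takes ≈40 s on one CPU core; the end-to-end acceptance
script ≈1 min. Learnability checks run three seeds and require ≥0.90
validation patch accuracy from each.

Numerics: all float64; probability rows sum to 1 within 1e-9 (fixtures) /
1e-6 (network softmax); QC comparisons are strictly-less-than failures,
exactly as specified; grid anchoring and rounding conventions are stated
above; seeds flow from explicit integer seeds through NumPy generators
(per-stage seeds in the pipeline are derived from the global seed and the
stage name, so stage re-runs are order-independent).

## Known limitations

- The CNN is deliberately small; it is not an EfficientNet and makes no
  claim to its ImageNet-scale behavior beyond sharing the compound-scaling
  rule.
- Determinism is exact only single-threaded; multi-threaded BLAS may
  reorder reductions.
- The tiler targets single-resolution raster images; whole-slide pyramid
  formats and region streaming are out of scope.
- Synthetic renders cannot validate stain-normalization or
  domain-shift behavior.
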