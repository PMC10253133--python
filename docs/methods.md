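# Methods

## Overview

`tmascreen` re-implements, as a scripted and tested pipeline, a digital-
pathology workflow for screening MLH1-immunostained colorectal tissue-
microarray (TMA) cores. Each core receives a histology call (normal
epithelium vs tumour) and an MLH1 status (proficient vs deficient);
cores that cannot be certified at a pre-agreed evidence threshold are
flagged for pathologist review rather than silently mis-called. The
stages run in a fixed order:

1. colour deconvolution of the brightfield RGB image into haematoxylin
   and DAB optical-density channels;
2. positive cell detection on the haematoxylin channel, with a single
   DAB threshold assigning each cell a Positive/Negative base class;
3. Gaussian neighbourhood ("smoothed") features;
4. random-forest tissue classification into four classes (normal
   epithelium, tumour, immune infiltrate, stroma);
5. TMA dearraying (grid location, labelling A1–I18, validity calls);
6. per-core certification at the ≥75% threshold;
7. agreement statistics against reference labels.

A synthetic TMA generator provides images plus per-cell and per-core
ground truth, so every stage is exercisable with no external data.

## Staining model and colour deconvolution

Brightfield stains obey the Beer–Lambert law: per RGB channel,
OD = −log10(I / I₀) with I₀ the calibrated white point, and stain
contributions add linearly in OD. With unit stain vectors as rows of a
matrix M, a pixel with concentrations c has OD vector c·M; deconvolution
solves the 3×3 system per pixel and clamps negative concentrations to
zero. Defaults are the calibrated H-DAB vectors
haematoxylin (0.67253, 0.56452, 0.47856), DAB (0.25141, 0.41193,
0.87585), background (235, 232, 239); the residual vector is their
normalised cross product. OD uses the base-10 logarithm, with input
intensity clamped at 1 so a black pixel maps to log10(I₀) rather than
infinity.

**Quantisation.** 8-bit composition then deconvolution recovers
concentrations to within 0.02 OD for concentrations up to ≈0.8 per
stain. The error is pure quantisation — ΔOD ≈ 0.5/(I·ln 10) per channel
— and grows as channels darken; above ≈1 OD total per channel the 0.02
bound no longer holds. Tests and the acceptance script therefore probe
the [0, 0.8]² working range, which covers typical nuclear OD.

**Stain-vector estimation** uses an angular-percentile method: pixels
with OD vector norm ≥ 0.15 are projected onto the plane of their top two
principal components, and the 1st/99th percentile angular directions are
taken as the stain vectors (the vector with the larger red-channel
component is reported as haematoxylin). This recovers a generating
matrix to within 3° when the scene contains near-pure pixels of each
stain. It is an identifiability limit, not an implementation one: on
cores where every DAB deposit co-localises with full counterstain there
is no pure-DAB direction in the data, and the estimated DAB vector can
sit 10–18° off however the percentile is chosen. The haematoxylin
vector — the detection channel — remains accurate (<3°) on such cores.

## Positive cell detection

Detection runs on the haematoxylin OD channel (DAB is not subtracted
first). Defaults follow the calibrated settings for MLH1 on colorectal
tissue at 0.5 μm/px: background radius 8 μm, median radius 0 (skipped),
Gaussian σ 1.5 μm, area gate 10–400 μm², detection threshold 0.1 OD,
maximum background intensity 2 OD, shape-based splitting on, cell
expansion 5 μm, boundary smoothing on, score compartment "nucleus DAB OD
mean", positive threshold 0.2 OD, single threshold.

Pipeline: optional median filter → Gaussian smoothing → background
estimate by grayscale morphological opening with a disc of the
background radius (pixels whose background exceeds the maximum
background intensity are excluded as non-tissue) → threshold → hole
filling → watershed split on the smoothed distance transform with
h-maxima suppression (h = 0.5 μm, 8-connectivity, ties to the lowest
label) → area gate.

Numerical choices:

* The opening uses scikit-image's disc *sequence decomposition*, exact
  enough that its error (<0.04 OD on smooth fields) sits far below the
  detection threshold while keeping the cost near-linear in image size.
  An earlier downsampled opening left resize artifacts at strong edges
  that fabricated ring-shaped detections around oversized nuclei.
* Smoothing is for *detection*; object boundaries are then refined to
  the raw background-subtracted support (per label, holes filled).
  Without this, a σ=1.5 μm blur inflates the thresholded support of a
  3 μm nucleus by ~30% in area. With it, a disc of known radius is
  recovered within pixelation error, and a 12 μm-radius object (452 μm²)
  is correctly removed by the 400 μm² gate.
* Cell expansion uses nearest-nucleus Euclidean label expansion, so
  neighbouring cells share an equidistant boundary and never overlap;
  cytoplasm = cell minus nucleus. An empty compartment yields a missing
  (NaN) feature, not a dropped cell.
* Circularity is 4πA/P² with the Crofton perimeter; on discretised
  discs it converges to ≈0.97 from below, so identity checks use
  radius ≥ 6 μm.
* A cell whose score compartment is missing is marked Unscored, warned
  about, and excluded from core summaries.

Positivity is inclusive (score ≥ 0.2 → Positive): the printed threshold
grading convention treats the boundary value as staining.

## Smoothed features and tissue classification

For cell i and raw feature f, the smoothed value is the Gaussian
distance-weighted average over cells j within 3σ (including i), with
w_ij = exp(−d²/2σ²) and σ = FWHM/2.3548, FWHM 25 μm by default. Pooling
is restricted to neighbours sharing the Positive/Negative *base* class
(config flag `same_base_class`; the unrestricted variant is available
because the restriction's referent is ambiguous in the source workflow).
A cell with no eligible neighbour keeps its raw value; NaN features are
ignored in the averages. Smoothing is a convex combination, so smoothed
values stay inside the neighbourhood's raw range.

The classifier is a random forest (100 trees, √p features per split, no
depth limit, seeded; out-of-bag accuracy recorded in the model
manifest) over all raw + smoothed features: nucleus area, circularity,
nucleus haematoxylin OD mean, nucleus/cell/cytoplasm DAB OD means.
Training detections come from a montage of annotated 500 μm × 500 μm
regions laid out row-major with 50 μm background gutters — wider than
the 3σ smoothing reach, so features never mix across regions. Tie-breaks
in prediction follow the fixed class order (normal epithelium, tumour,
immune infiltrate, stroma). The marker base class is never altered by
classification; the (tissue, marker) pair forms the composite class.

## Dearraying

Tissue is any pixel whose summed OD reaches 0.1, minus objects under
100 μm²; the mask is computed on a view downsampled to ≈4 μm/px, ample
for 0.9 mm cores and cheap for whole slides. Candidate cores are tissue
blobs within [1%, 400%] of the nominal core area; a complete regular
grid (defaults 9×18, pitch 0.9 mm) is fitted per axis by iterated
least squares of blob centres on their rounded grid indices, so blank or
missing positions still receive labelled grid cells. Each core's tissue
fraction is measured in a disc scaled by the bounds factor (105% → disc
of 945 μm), and the core is valid when that fraction, as a percent,
reaches the density threshold (5.0). The density threshold is read as
*percent coverage* and the bounds scale as *percent disc scaling* —
the source workflow does not state units for either. Manual adjustments
(move/invalidate) come from a plain CSV override table, keeping runs
scriptable; moving a core recomputes its tissue fraction.

Cells are assigned to the valid core disc containing their centroid
(scaled diameter); cells outside every valid disc are unassigned and
never certified. The fit is translation-invariant and, because OD is
referenced to the calibrated white point, invariant to uniform scanner
gain. Rotations are not modelled (the generator is axis-aligned; the
fit tolerates only small rotations).

## Certification

Per core, cells are tallied by tissue class; the marker tally is over
epithelial cells only (normal epithelium + tumour), because stromal and
immune cells express MLH1 regardless of tumour status and would
confound the call. Histology and MLH1 status are assessed independently:

* fewer than `min_cells` (20) classified cells → **Invalid**;
* histology certifies Normal/Tumour when that class reaches ≥75% of the
  denominator (default: all classified cells; epithelial-only is a
  config alternative — the two readings change flag rates, so both are
  exposed);
* MLH1 certifies Proficient/Deficient when the positive/negative
  fraction of epithelial cells reaches ≥75%;
* both certain → the combined call; one or both uncertain → **Flagged**
  with the uncertain dimension(s) as the reason.

At any threshold above 0.5 at most one class per dimension can reach it,
so certification is unambiguous by construction, and raising the
threshold can only move cores toward flagging (monotonicity). A
certified "MLH1-deficient normal epithelium" is representable but
biologically unexpected; it raises a warning, not an error. The
`min_cells = 20` floor replaces interactive manual invalidation of
near-empty cores with a reproducible rule.

## Agreement statistics

Flagged and invalid cores are excluded, the rest cross-tabulated against
reference labels for a positive class (default: MLH1-deficient tumour).
Sensitivity and specificity carry exact Clopper–Pearson 95% intervals
(beta quantiles; at k = n the lower bound is (α/2)^(1/n)). Cohen's
kappa uses po = (tp+tn)/n, pe from the margins, κ = (po−pe)/(1−pe), with
the asymptotic Wald interval κ ± z·√(po(1−po)/(n(1−pe)²)) — the upper
bound is deliberately not truncated at 1, matching conventional
statistical-package output; the κ=0 test is the Wald z. Display follows
clinical style: percentages to 2 decimals, κ to 3.

`reconstruct_confusion` recovers an integer 2×2 table from printed
marginals (classified n, false-positive count, sensitivity 100%, rounded
specificity); for n = 74, fp = 1, specificity 98.25% the unique solution
is tp = 17, fn = 0, fp = 1, tn = 56. The package's agreement report on
this table is what the acceptance script recomputes.

## Synthetic TMA generator

The generator defines the study conditions for all end-to-end tests:
a 9×18 grid, 0.9 mm pitch, 0.6 mm tissue cores, 0.5 μm/px, with 74
unambiguous cores (17 MLH1-deficient tumours, 29 proficient tumours,
28 proficient normals — mirroring the reference cohort's proportions),
25 ambiguous cores (5 per ambiguity pattern) and 63 blanks, shuffled
deterministically by seed.

Per core: nucleus count ~ Poisson(density × tissue area), default
density 2000 cells/mm² (a moderate value for colonic mucosa at this
resolution); centres from a dart-throwing hard-core process (minimum
spacing 1.5× the composition-weighted mean radius, at most 10× the
target count of darts, failure with a diagnostic if fewer than 90% are
placed). Each nucleus is an ellipse with class-dependent morphology:

| class             | radius μm (mean ± SD) | axis ratio | H OD |
|-------------------|----------------------|-----------|------|
| normal epithelium | 3.5 ± 0.4            | 1.3       | 0.60 |
| tumour            | 5.0 ± 0.7            | 1.8       | 0.75 |
| immune infiltrate | 2.4 ± 0.25           | 1.1       | 0.90 |
| stroma (spindle)  | 3.8 ± 0.5            | 3.0       | 0.50 |

Marker-positive nuclei additionally deposit DAB (mean 0.6 OD). A
uniform haematoxylin "tissue wash" of 0.15 OD covers the tissue disc,
modelling cytoplasmic/matrix counterstain uptake; it is what makes cores
visible to area-based tissue detection (nuclei alone cover <5% of a
core disc). Gaussian OD noise (σ = 0.02) is added before composition to
8-bit RGB, so noise is multiplicative in intensity, as stain physics
dictates. Every core draws from an RNG stream derived from (seed, grid
index): renders are byte-identical across runs and independent of
evaluation order.

The five ambiguity scenarios encode the flag-reason taxonomy at the
composition level, so flagging follows from the certification rule
itself rather than from fragile classifier failure: scant tissue
(fill 25%, mixed 50/30/20 histology), atypical tumour morphology
(55% tumour with nuclei shrunk toward the normal range), heavy immune
infiltrate (45% immune), normal-only mucosa (60% normal / 35% stroma),
and weak/patchy staining (85% tumour but 55% marker-positive with a
sinusoidal DAB multiplier of amplitude 0.5 and 250 μm wavelength).
Expected calls are set by the scenario factories — for the patchy
scenario the truth fractions and measured fractions differ by design,
so the expected call cannot be derived from composition alone.

**What the generator does not model:** photorealistic texture, chromatin
structure, out-of-focus blur, scanner artefacts, tissue folds, nuclear
overlap in z, or chromogen masking of the counterstain (positive nuclei
here retain full haematoxylin). Passing tests therefore demonstrate
that the pipeline's logic and calibrated parameters behave as specified
under controlled staining physics — not that the classifier's accuracy
transfers to real histology, which requires training on real annotated
regions.

## Problem sizes and determinism

The end-to-end acceptance run uses the full 9×18 grid at 0.5 μm/px
(a 32400 × 16200 slide, ≈53 000 ground-truth cells). Detection runs
per core on cropped tiles and the dearray mask on a downsampled view,
keeping peak memory near the 1.6 GB slide buffer. Unit tests use
smaller grids (2×2 to 3×5) and coarser pixel sizes where the property
under test allows it. All randomness flows from named seeds (simulation
per-core streams, forest seed in the config); reruns with the same seed
produce identical call tables.

## Known limitations

* Heavily overlapping, co-aligned nuclei merge into single detections;
  at default density ~5–15% of nuclei sit in such pairs or chains
  depending on class morphology. Class *fractions* — what certification
  consumes — are far less affected than counts, which is the design's
  tolerance argument. Count-accuracy guarantees hold in the separable
  regime (sparse cores, ≈300 cells/mm²).
* The dearrayer assumes an axis-aligned grid; rotated arrays beyond ~2°
  are out of scope.
* DAB-vector estimation needs near-pure chromogen pixels (see above).
* Parameter semantics, not bit-level behaviour, of the original
  interactive tooling are reproduced; the background estimator,
  watershed variant and forest implementation are this package's own
  documented choices.
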