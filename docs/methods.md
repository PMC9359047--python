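# Methods

## Problem setting

Knowledge-based planning (KBP) for pelvic IMRT rests on one premise:
patients with similar anatomy — in particular, a similar spatial
relationship between the target and each organ at risk — can achieve
similar organ sparing. `kbplan` implements the retrieval half of that
loop: align the new patient's PTV to every database patient's PTV, score
anatomical similarity with the Dice coefficient, and transfer the achieved
dose–volume parameters of the best matches as optimization constraints.
Plan creation itself (beam placement, ring structures, inverse
optimization in a treatment-planning system) is out of scope; the package
emits a TPS-agnostic JSON objective file instead.

## Grids, masks and coordinates

All volumes live on axis-aligned voxel grids in DICOM LPS millimetre
coordinates, array axes ordered (x, y, z), 0-based indices, with the grid
origin at the *center* of voxel (0,0,0). Membership is decided at voxel
centers. Database patients with heterogeneous CT grids are resampled
(nearest voxel-center lookup for masks, trilinear for dose) to a common
isotropic grid, 2.5 mm by default — a registration over one shared lattice
requires commensurate grids, and 2.5 mm is a typical dose-grid resolution
for this site. RTSTRUCT contours are rasterized with the even–odd rule at
voxel centers; multiple polygons on a slice XOR-combine so inner contours
cut holes. Points exactly on a polygon edge fall where floating point puts
them; test fixtures avoid such ties.

## Registration

The translation-only alignment maximizes the overlap count
`S(t) = Σ_x fixed(x)·moving(x − t)` over all integer translations `t`.
Numerical choices:

- **Linear, not circular, correlation.** Both masks are zero-padded to
  `N_fixed + N_moving − 1` per axis before the FFT. Padding only "up to the
  same size" would wrap large offsets around the grid and corrupt their
  scores; full padding makes every entry of the score volume the true
  aperiodic overlap, including the single-voxel corner overlaps at the
  extreme offsets.
- **Integer rounding.** The inverse FFT is rounded to the nearest integer
  (and floored at 0) because the true values are voxel counts; this removes
  float noise and makes tie handling exact. The test suite asserts
  elementwise equality with a direct spatial-domain evaluation on hundreds
  of random pairs.
- **Tie-breaking.** Among translations with maximal overlap: smallest
  Euclidean displacement in mm first, then lexicographic (u, v, w). Both
  rules are arbitrary but deterministic across FFT backends; symmetric
  masks therefore register to (0, 0, 0).
- **Bounding-box cropping.** `register_translation` crops both masks to
  their occupied bounding boxes before the FFT and shifts the recovered
  translation back. This is exact — all-zero planes contribute nothing to
  any overlap, and a nonempty pair always overlaps somewhere inside the
  cropped range — and reduces an 81-patient match from minutes to seconds.
- No rotation, no sub-voxel refinement: binary masks at 2.5 mm gain little
  from sub-voxel shifts, and the retrieval only needs a similarity ranking,
  not a precise transform.

## Similarity and selection

`score_pair` applies the *single* PTV-registration translation to the
candidate's rectum and bladder before computing their Dice scores. This is
deliberate: re-registering each organ separately would destroy exactly the
PTV–organ geometric relationship the similarity is supposed to measure.

`match_patient` runs the two-stage cascade (top `k_ptv = 20` by PTV DSC,
then top `k_oar = 3` per organ, rectum and bladder ranked independently).
Ties in any ranking break by ascending patient ID for determinism.
Leave-one-out is enforced by ID comparison. The derived constraint per
organ is the *minimum* achieved V50Gy among its top-3 — the most ambitious
target that a demonstrably similar patient actually reached — and is used
as-is, not floored at the protocol value. All other objective rows are
copied verbatim from the protocol template.

## DVH metrics

Cumulative DVHs use inclusive thresholding (`dose ≥ d`) on fixed-width
bins (0.05 Gy default); the sorted voxel doses are retained on the curve so
`VxGy` is exact rather than interpolated. `Dx` is read from the binned
curve: the smallest dose at which the curve drops below x %, linearly
interpolated between bracketing edges — for a curve sitting exactly at x %
over a dose plateau this returns the plateau's upper edge, matching the
"minimum dose to the hottest x %" convention. `Dmax` is the maximum
single-voxel dose, not a near-max volume dose; with the fine dose grids
used here the difference is small, and the choice is isolated in one
function. `HI = 100·(D2 − D98)/D_Rx` with D_Rx = 50 Gy. The paired cohort
comparison reports mean difference, SD, t and two-sided p with n−1 degrees
of freedom; identical cohorts give p = 1, and a zero-variance nonzero
difference is flagged degenerate with p = 0 rather than raising.

## Synthetic cohorts

The generator stands in for a clinical plan database so the pipeline is
testable end to end.

**Anatomy.** Each phantom is rasterized on the default 96×96×64 grid at
2.5 mm (240×240×160 mm field of view): an ellipsoidal PTV (semi-axes
45×35×40 mm) centered mid-pelvis; a spherical bladder (27 mm) anterior and
slightly superior; a tubular rectum (radius 12 mm, length 100 mm) running
inferior–superior behind the PTV; spherical femoral heads (20 mm) at
±80 mm laterally; a 5 mm spinal-cord tube posterior on the midline. The
bladder and rectum positions are driven by an `overlap` control in [0, 1]:
0 leaves a 3 mm gap to the PTV surface (empty intersection), larger values
push the organ into the PTV. Per-patient jitter draws center offsets
(±6 mm), size factors (±15 %) and overlap controls (uniform 0.35–0.95)
from a seeded generator; cohort generation is a pure function of its seed.
The overlap range was chosen so most patients have a clinically plausible
nonzero organ V50Gy, mirroring the spread seen in treated pelvic cohorts.

**Dose surrogate.** The achievable dose is a sigmoid of the signed
Euclidean distance `s(x)` from the PTV surface (negative inside, from two
complementary distance transforms with physical spacing):

```
D(x) = (1 + h) · D_Rx / (1 + exp(s(x)/σ)) + ε,   ε ~ N(0, noise²)
```

with σ = 1.5 mm and hotspot factor h = 0.08 by default (D_max ≈ 54 Gy on a
50 Gy prescription). The hotspot term is essential: a pure sigmoid
saturates strictly *below* the prescription, so every V50Gy — target and
organs alike — would be identically zero and constraint transfer would be
vacuous. With h > 0 the 50 Gy isosurface sits at `s* = σ·ln(h)` (≈ −3.8 mm
inside the PTV surface), making each structure's V50Gy an exact, smooth
function of its geometry relative to the PTV: with noise = 0,
`V50 = fraction of structure voxels with s(x) ≤ s*`, an identity the tests
assert against the DVH route to machine precision. That smooth
anatomy→dose dependence is precisely the premise KBP relies on, which is
what makes parameter-recovery acceptance tests meaningful.

**What the surrogate does not model.** Beam geometry, fluence modulation,
tissue heterogeneity, and optimizer trade-offs between competing organs.
Its PTV coverage is also unrealistic (V50Gy ≈ 60–80 % instead of > 96 %),
since the 50 Gy surface lies inside the PTV — irrelevant for the matching
problem, but a reason the synthetic goal reports fail the PTV coverage
goal by design. Synthetic Dice values run higher than is typical for clinical cohorts
(median top-20 PTV DSC ≈ 0.9 here) because phantoms drawn from one
parametric family are more alike than real patients; passing tests therefore demonstrate correctness of the machinery
and recoverability of the anatomy→dose relationship, not clinical
performance.

## Problem sizes

The test suite and acceptance script use: oracle comparisons on masks up
to 16³ (the spatial-domain oracle scales with the sixth power of side
length); shift recovery on 24³ masks; cohort-scale checks on 81 patients
at the default 2.5 mm grid with 20 leave-one-out test cases and 10
random-selection replicates; pipeline/CLI tests on a reduced 72×72×48 grid
at 3.5 mm. These sizes were chosen so the full suite runs in a few minutes
on one CPU while still exercising the cohort scale the two-stage selection
(20 → 3) was designed for.

## Known limitations

- Translation-only registration cannot credit similar anatomies at
  different rotations or scales.
- Dice on binary masks ignores *where* inside the organ the overlap occurs
  relative to the high-dose region; two patients with equal DSC can have
  different achievable sparing.
- The constraint transfer takes a minimum over three values and is
  therefore sensitive to a single outlier patient with an atypically low
  achieved V50Gy.
- DICOM support covers planar CLOSED_PLANAR RTSTRUCT contours and
  grid-aligned RTDOSE volumes (identity orientation); oblique orientations
  are not handled.
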