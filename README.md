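# kbplan — knowledge-based radiotherapy planning by anatomical matching

`kbplan` implements a knowledge-based treatment-planning (KBP) engine for
pelvic intensity-modulated radiotherapy: given a new patient's contoured
anatomy, it retrieves the most anatomically similar patients from a database
of prior treatment plans and transfers their *achieved* organ-at-risk
dose–volume parameters as personalized optimization constraints. It is aimed
at medical-physics researchers who want a transparent, scriptable
implementation of similarity-based dose-constraint prediction without a
commercial treatment-planning system in the loop.

## Method

**Registration.** The planning target volume (PTV) of the test patient and
of each database patient are binary masks `I_test`, `I_match` on a common
voxel grid. Minimizing their squared voxelwise difference over integer
translations `(u, v, w)` is equivalent to maximizing the spatial correlation

```
S(u, v, w) = Σ_x I_test(x) · I_match(x − (u, v, w)),
```

the overlap voxel count after shifting the candidate mask. `kbplan`
evaluates `S` for *all* translations at once by zero-padding both masks to
the full linear-correlation size (`N_fixed + N_moving − 1` per axis),
multiplying the FFT of the fixed mask with the conjugate FFT of the moving
mask, and inverting — then rounding to integer counts. A direct
spatial-domain evaluation (`brute_force_correlation`) serves as an
independent oracle in the tests.

**Similarity and selection.** After PTV alignment, the candidate's PTV,
rectum and bladder (moved by the single PTV translation, preserving each
patient's PTV–organ geometry) are compared with the test patient's by the
Dice similarity coefficient, `DSC = 2|A∩B| / (|A|+|B|)`. Selection is a
two-stage cascade: the top 20 patients by PTV DSC advance, then the rectum
and bladder are ranked independently and the top 3 per organ are kept.

**Constraint transfer.** The smallest achieved `V50Gy` (percent of the organ
receiving ≥ 50 Gy) among an organ's top-3 matches becomes that organ's
optimization constraint; all other objective rows come from the
institutional protocol template (PTV uniform 50 Gy, D_min 49.5 Gy, D_max
52 Gy, min V50Gy 96 %; femoral heads V45Gy 5 %; small intestine V45Gy 10 %,
D_max 50 Gy; cord D_max 42 Gy).

**Evaluation.** Cumulative DVHs give `VxGy`, `Dx` (dose to the hottest x %),
`Dmax`, and the homogeneity index `HI = (D2 − D98)/D_Rx × 100 %`; plans are
flagged against the clinical goals (PTV V50Gy > 96 %, rectum/bladder
V50Gy < 50 %, femoral heads and small intestine V50Gy < 10 %, small
intestine D_max < 52 Gy, cord D_max < 45 Gy), and paired cohorts are
compared with a paired t-test.

Because no clinical database ships with the package, a `synthetic` module
generates reproducible pelvic phantom cohorts (jittered ellipsoidal PTV,
spherical bladder, tubular rectum, femoral heads, cord) with a
sigmoid-of-distance achievable-dose surrogate, so every stage is testable
end to end. See `docs/methods.md` for the model details and its limits.

## Worked example

`python examples/match_and_transfer.py` builds a 31-patient synthetic
cohort, holds one patient out, and matches it against the rest:

```
test patient: P000
top 5 PTV matches (id, PTV/rectum/bladder Dice):
  P002: 0.953 / 0.518 / 0.749
  P008: 0.952 / 0.635 / 0.622
  ...
rectum top-3:  ['P008', 'P020', 'P015']
bladder top-3: ['P002', 'P015', 'P010']
own achievable rectum V50Gy:  16.6%
own achievable bladder V50Gy: 20.4%
personalized objective set:
  ...
  rectum           V50Gy        10.0465 %
  bladder          V50Gy        9.49153 %
```

The transferred rectum constraint (10.0 %) is the smallest achieved V50Gy
among the three patients whose rectum geometry (after PTV alignment) best
matches the test patient's — a constraint an optimizer should be able to
meet, since anatomically similar patients met it. The other examples
(`register_and_score.py`, `evaluate_plan_dvh.py`) demonstrate the
registration and DVH layers in isolation.

A thin CLI wraps the same functions for file-based workflows:

```
kbplan simulate --out sim --n 81 --seed 1
kbplan build-db --in sim --out db
kbplan match --test db/P000 --db db --out out
kbplan evaluate --dose dose.nii.gz --structs db/P000 --out eval
```

`build-db` also accepts directories of DICOM RTSTRUCT/RTDOSE files.

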