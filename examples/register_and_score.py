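"""Align one patient's PTV to another's and score anatomical similarity.

Builds two synthetic pelvic phantoms whose anatomies differ by jitter,
recovers the best integer-voxel translation of one PTV onto the other by
FFT correlation, and reports the Dice similarity of PTV, rectum and bladder
after the shift.  A Dice of 1.0 would mean voxel-identical structures; the
values printed here quantify how anatomically alike the two patients are.
"""

from kbplan import PhantomParams, dice, make_phantom, register_translation
from kbplan.registration import apply_translation
from kbplan.synthetic import DEFAULT_GRID

fixed = make_phantom(PhantomParams(patient_id="A", center_jitter=6, size_jitter=0.1, seed=1))
moving = make_phantom(PhantomParams(patient_id="B", center_jitter=6, size_jitter=0.1, seed=2))

result = register_translation(fixed["PTV"], moving["PTV"])
mm = [t * s for t, s in zip(result.translation, DEFAULT_GRID.spacing)]
print(f"recovered translation: {tuple(result.translation)} voxels = {mm} mm")
print(f"PTV overlap at optimum: {result.score} voxels")

for name in ("PTV", "rectum", "bladder"):
    before = dice(fixed[name], moving[name])
    after = dice(fixed[name], apply_translation(moving[name], result.translation))
    print(f"{name:8s} Dice before/after alignment: {before:.3f} / {after:.3f}")
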