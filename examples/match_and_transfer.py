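"""Retrieve similar patients from a cohort and transfer dose constraints.

Generates a 30-patient synthetic database with achieved rectum/bladder
V50Gy values, runs the two-stage match (top-10 by PTV Dice, then top-3 per
organ) for a held-out patient, and prints the personalized optimization
objectives: the minimum achieved V50Gy among each organ's best matches
becomes that organ's constraint, everything else follows the protocol
template.  Lower transferred V50Gy values mean the optimizer will be pushed
toward the sparing that anatomically similar patients actually achieved.
"""

from kbplan import derive_constraints, make_database, match_patient
from kbplan.core import VoxelGrid

grid = VoxelGrid((72, 72, 48), (3.5, 3.5, 3.5), (1.75, 1.75, 1.75))
cohort = make_database(31, seed=42, grid=grid)
test, database = cohort[0], cohort[1:]

selection = match_patient(test, database, k_ptv=10, k_oar=3)

print(f"test patient: {test.patient_id}")
print("top 5 PTV matches (id, PTV/rectum/bladder Dice):")
for rec in selection.ptv_top[:5]:
    d = rec.dsc
    print(f"  {rec.database_patient_id}: {d['PTV']:.3f} / {d['rectum']:.3f} / {d['bladder']:.3f}")
print(f"rectum top-3:  {selection.rectum_top}")
print(f"bladder top-3: {selection.bladder_top}")
print(f"own achievable rectum V50Gy:  {test.achieved_dvh[('rectum', 'V50Gy')]:.1f}%")
print(f"own achievable bladder V50Gy: {test.achieved_dvh[('bladder', 'V50Gy')]:.1f}%")

objectives = derive_constraints(selection, database)
print("personalized objective set:")
for structure, metric, value, units in objectives.entries:
    print(f"  {structure:16s} {metric:12s} {value:g} {units}")
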