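"""Evaluate a plan's DVH metrics against the clinical dose goals.

Builds one phantom, simulates its achievable dose with the sigmoid-of-
distance surrogate, and prints every plan-quality metric (PTV V50Gy, D98,
D95, D2, homogeneity index; organ V50Gy and maximum doses) next to its
pass/fail goal.  V50Gy is the percent of a structure receiving at least
50 Gy; HI = (D2 - D98)/50 Gy x 100%, smaller meaning a flatter target dose.
"""

from kbplan import PhantomParams, evaluate_plan, make_phantom, synth_dose
from kbplan.core import VoxelGrid
from kbplan.synthetic import DoseModelParams

grid = VoxelGrid((72, 72, 48), (3.5, 3.5, 3.5), (1.75, 1.75, 1.75))
patient = make_phantom(PhantomParams(rectum_overlap=0.6, bladder_overlap=0.5), grid)
dose = synth_dose(patient, DoseModelParams(prescription=50.0, sigma=1.5, hotspot=0.08))

metrics, goals = evaluate_plan(dose, patient, prescription=50.0)

print("plan metrics:")
for (structure, metric), value in sorted(metrics.items()):
    unit = "%" if metric.startswith(("V", "HI")) else "Gy"
    print(f"  {structure:16s} {metric:6s} {value:7.2f} {unit}")
print("goal report:")
for row in goals:
    flag = "PASS" if row["passed"] else "FAIL"
    print(f"  {row['structure']:16s} {row['metric']:6s} "
          f"{row['value']:7.2f} vs {row['goal']:>6s}  {flag}")
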