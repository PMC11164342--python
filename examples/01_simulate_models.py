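"""Simulate CA-125 under the two-cell-type and adaptive-dynamics models.

Builds a two-line chemotherapy schedule (21-day cycles), runs the
sensitive/resistant model, its single-cell special case, and the
adaptive-dynamics model from the same starting CA-125, and prints the level
at a few milestones. CA-125 falls while on treatment (sensitive cells die at
delta_S) and regrows between lines (growth rates gamma); the resistant
compartment makes later declines shallower.
"""
import numpy as np

from ca125kin import ADParams, SRParams, simulate_ad, simulate_single, simulate_sr
from ca125kin.cohort import TreatmentLine, TreatmentSchedule

schedule = TreatmentSchedule(lines=(
    TreatmentLine(1, tuple(7.0 + 21 * i for i in range(6)), ("carboplatin+paclitaxel",) * 6),
    TreatmentLine(2, tuple(300.0 + 21 * i for i in range(4)), ("carboplatin",) * 4),
))
C0 = 300.0
days = np.array([0.0, 112.0, 300.0, 363.0, 500.0])

sr = simulate_sr(
    SRParams(gamma_R=0.01024, gamma_S=0.0142, delta_R=-0.00018, delta_S=0.04421, R0=30.0),
    schedule, C0, days,
)
single = simulate_single(0.0142, 0.04421, schedule, C0, days)
ad = simulate_ad(
    ADParams(gamma_R=0.01024, gamma_S=0.0142, delta_R=-0.00018, delta_S=0.04421,
             A_gamma=0.3, A_delta=-0.2, B_gamma=1.0, B_delta=1.0),
    schedule, C0, days,
)

print("day      SR (R0=30)   single-cell   adaptive (x)")
for i, d in enumerate(days):
    print(f"{d:6.0f}  {sr.C[i]:11.1f}  {single.C[i]:12.1f}  {ad.C[i]:8.1f} ({ad.x[i]:+.3f})")
print()
print("Units are U/mL of CA-125. The single-cell model keeps dropping at the")
print("same rate in line 2; the SR model's resistant cells (delta_R < 0) blunt")
print("the second response; the adaptive model's resistance level x climbs")
print("during treatment and relaxes between lines.")
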