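"""Simulate the stimulated Regnase-1 circuit from resting cells.

Builds the packaged pulse profile (basal tone 0.05, ramp to full signal
between 0.25 and 0.5 h, then sustained), starts both genotypes from
their pre-stimulation steady state and prints total / free Regnase-1 and
Il6 mRNA at the immunoblot/qPCR time points.
"""

import numpy as np

from reg1dyn import Genotype, initial_condition_basal, integrate, signal_at
from reg1dyn.defaults import default_parameters, default_signal_profile

params = default_parameters()
profile = default_signal_profile()
times = np.array([0.0, 0.5, 2.0, 4.0])

print("time [h]   signal   " + "".join(f"{g.value:>28s}" for g in Genotype))
print(" " * 19 + "   total    free     Il6" * 2)
courses = {}
for g in Genotype:
    x0 = initial_condition_basal(params, g, profile.s_base)
    courses[g] = integrate(params, g, profile, x0, 4.0, times)

for i, t in enumerate(times):
    row = f"{t:7.1f} {signal_at(profile, t):8.2f}  "
    for g in Genotype:
        x1, _, x3, x4 = courses[g].states[i]
        row += f"  {x3 + x4:7.3f} {x3:7.3f} {x1:7.3f}"
    print(row)

wt = courses[Genotype.WT].states
total = wt[:, 2] + wt[:, 3]
print(
    f"\nWild type: total Regnase-1 drops from {total[0]:.3f} to {total[1]:.3f} "
    "within 30 min of stimulation (signal-driven degradation outpaces the "
    f"lagging resupply), then overshoots to {total[3]:.3f} by 4 h as induced "
    "Zc3h12a mRNA feeds translation."
)
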