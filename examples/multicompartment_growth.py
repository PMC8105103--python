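"""Grow the multicomponent tumor from a 2 mm^3 seed and watch it plateau.

The colony holds two active types (fast/radioresistant T1, slower/
radiosensitive T2), a quiescent pool Q fed by both, and a non-dividing pool
ND cleared into the blood.
"""

import numpy as np

from lungrt import CompartmentParams, TumorState, simulate_mcm

params = CompartmentParams.default()
init = TumorState.default_init()  # V1 = V2 = 1 mm^3, Q = ND = 0
times = np.linspace(0.0, 120.0, 241)
traj = simulate_mcm(params, init, times)

print("day     T1      T2       Q      ND    total  (mm^3)")
for day in (0, 10, 20, 40, 80, 120):
    i = int(day * 2)
    row = traj.states[i]
    print(f"{day:>3} {row[0]:>7.1f} {row[1]:>7.1f} {row[2]:>7.1f} "
          f"{row[3]:>7.1f} {row.sum():>8.1f}")

final = traj.final_state
print(f"\nsteady state: T1={final.V[0]:.0f}, T2={final.V[1]:.0f}, "
      f"Q={final.V_Q:.0f}, ND={final.V_ND:.0f} mm^3")
print("each active type saturates below its carrying capacity because the")
print("quiescent and non-dividing pools continuously drain active volume")
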