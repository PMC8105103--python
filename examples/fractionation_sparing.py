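"""The fractionation-sparing effect of the linear-quadratic model.

With growth switched off, splitting a fixed total dose D into n fractions
leaves survival exp(-alpha D - beta D^2 / n): the quadratic term shrinks
with n, so heavily fractionated courses spare cells — dramatically so for
a low alpha/beta (radioresistant) population.
"""

import numpy as np

from lungrt import (
    CompartmentParams,
    Fraction,
    FractionationPlan,
    RadiosensitivityParams,
    TumorState,
    simulate_course,
)

growth_off = CompartmentParams(
    a=[0.0, 0.0], K=[1.0, 1.0], p_Qm=[0.0, 0.0], p_mQ=[0.0, 0.0],
    p_mND=[0.0, 0.0], p_QND=0.0, eta=0.0,
)
rs = RadiosensitivityParams.default()
init = TumorState(V=[100.0, 100.0], V_Q=100.0)

D = 60.0
print(f"total dose {D:.0f} Gy split into n fractions (growth off)")
print("  n   T1 survival (sim)   closed form")
for n in (1, 4, 5, 8, 30):
    plan = FractionationPlan([Fraction(float(i), D / n) for i in range(n)])
    _, result = simulate_course(growth_off, rs, plan, init)
    closed = np.exp(-(rs.alpha[0] * D + rs.beta[0] * D**2 / n))
    print(f"{n:>3}   {result.ratio['T1']:>17.3e}   {closed:>11.3e}")

print("\nsurvival rises ~95 orders of magnitude between 1 and 30 fractions")
print("for the alpha/beta ≈ 3 Gy compartment: the biological rationale for")
print("large-dose-per-fraction (SBRT/hypofractionated) schedules")
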