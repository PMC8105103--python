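"""Generate a noisy synthetic growth curve and recover its parameters.

A logistic curve (a = 0.502 / day, K = 1297 mm^3) is sampled at 20 time
points over 25 days, perturbed with 10% multiplicative log-normal noise,
and refit by nonlinear least squares.
"""

import numpy as np

from lungrt import DEFAULT_LOGISTIC, FixtureSpec, fit_growth_curve, generate_fixture

spec = FixtureSpec(
    model="logistic",
    params=DEFAULT_LOGISTIC,
    v0=1.0,
    times=tuple(np.linspace(0.0, 25.0, 20)),
    sigma=0.1,
    seed=42,
)
curve = generate_fixture(spec)
res = fit_growth_curve(curve, model="logistic")

print(f"true parameters:   a = {DEFAULT_LOGISTIC.a:.3f} / day, "
      f"K = {DEFAULT_LOGISTIC.K:.0f} mm^3")
print(f"fitted parameters: a = {res.params.a:.3f} / day, "
      f"K = {res.params.K:.0f} mm^3")
print(f"residual sum of squares: {res.rss:.1f} mm^6 over {res.n_points} points")
print(f"converged: {res.converged}, identifiable: {res.identifiable}")
print("\nthe carrying capacity is pinned by the late plateau points, so it")
print("recovers within a few percent; the rate a is more noise-sensitive")
print("(its Monte-Carlo 99.5% error bound at this noise level is ~43%)")
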