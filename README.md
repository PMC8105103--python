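# lungrt

Simulation of non-small-cell lung cancer (NSCLC) growth and fractionated
radiotherapy with a multicomponent ordinary-differential-equation model.

`lungrt` is aimed at radiobiology modellers and medical physicists who want
to explore how fractionation schedules — stereotactic body radiotherapy
(SBRT), conventional fractionation (CFRT), accelerated hyperfractionation
(HFRT) — trade off against tumor regrowth kinetics, without clinical data:
the whole pipeline runs on published parameter fits and synthetic curves.

## The model

**Growth.** The tumor volume is split into M active sub-populations
T₁…T_M (each logistic with its own rate a_m and carrying capacity K_m, so
the colony can mix radioresistant and radiosensitive clones), a quiescent
pool Q of cells that have suspended division but can re-enter the cycle,
and a non-dividing pool ND awaiting clearance into the blood at rate η:

```
dV_m /dt = a_m V_m (1 − V_m/K_m) + p_Qm V_Q − (p_mQ + p_mND) V_m
dV_Q /dt = Σ_m p_mQ V_m − (Σ_m p_Qm + p_QND) V_Q
dV_ND/dt = Σ_m p_mND V_m + p_QND V_Q − η V_ND
```

Volumes are mm³, times days; the transfer coefficients p_ij are first-order
rate constants (day⁻¹). Single-population logistic and Gompertz models are
included as baselines with closed-form solutions. Defaults are a published
two-compartment NSCLC fit (M = 2).

**Radiation.** A fraction of dose D (Gy) kills per the linear-quadratic
law, S = exp(−αD − βD²), with per-compartment (α, β) for the active types
and the quiescent pool; the non-dividing pool is immune. Because delivery
takes minutes against day-scale growth, each fraction is applied by default
as an instantaneous multiplication of V_m and V_Q by their survivals
(impulse mode); a finite-duration constant-dose-rate mode is available for
studying delivery-time effects. A course alternates free growth with timed
fractions built from prescription-style specs (total dose, fraction count,
fractions/day, treatment days/week).

**Metric.** Plans are scored by the treatment ratio — tumor volume after
the course divided by the volume before it (lower is better) — reported per
compartment and in total.

## Worked example

Delivering 60 Gy in 30 × 2 Gy fractions once daily (6 calendar weeks,
weekends off) versus twice daily (3 weeks), with the committed comparison
configuration:

```
$ python examples/hyperfractionation_headline.py
CFRT 60 Gy/30 Fr             course 39.00 d   T1 ratio 0.2381   total ratio 0.2340
HFRT 60 Gy/30 Fr BID         course 18.25 d   T1 ratio 0.0070   total ratio 0.0063
```

Same dose, same fractions — only the calendar shrinks — yet the
radioresistant compartment's treatment ratio collapses by a factor ~30,
because the shorter course denies the tumor its inter-fraction regrowth.
Other examples under `examples/` cover baseline growth curves, the
multicomponent plateau, the fractionation-sparing closed form, SBRT plan
comparison, and noisy-curve parameter recovery.

The same runs are available from the shell:

```
lungrt treat --preset cfrt-60-30 --config configs/cfrt_hfrt_headline.yaml --out run/
lungrt compare --presets sbrt
lungrt fixture --sigma 0.1 --seed 42 --out fx.csv && lungrt fit fx.csv
```

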