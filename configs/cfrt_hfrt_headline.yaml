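# Calibrated configuration for the CFRT-vs-accelerated-HFRT comparison:
# 60 Gy / 30 Fr at 2 Gy per fraction, once daily versus twice daily,
# 5 treatment days per week, impulse fractions.
#
# The tumor grows from a 2 mm^3 seed (1 mm^3 per active type) for 13 days
# before the first fraction, and each plan's T1 treatment ratio is read at
# day 30 after the course start (a common calendar horizon for both plans,
# taken just before any fraction delivered at that instant).  Under these
# conventions the once-daily plan gives a T1 ratio near 0.24 and the
# twice-daily plan near 0.007; this file is the regression anchor for that
# comparison.
compartments:
  a: [0.862, 0.501]
  K: [1397.0, 1174.0]
  p_Qm: [0.1, 0.1]
  p_mQ: [0.2, 0.2]
  p_mND: [0.2, 0.2]
  p_QND: 0.09
  eta: 0.4
radiosensitivity:
  alpha: [0.194, 0.3705]
  beta: [0.063, 0.02335]
  alpha_Q: 0.3
  beta_Q: 0.15
init:
  V: [1.0, 1.0]
  V_Q: 0.0
  V_ND: 0.0
run_in_days: 13.0
eval_day: 30.0
mode: impulse
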