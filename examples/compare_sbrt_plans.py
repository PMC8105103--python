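"""Compare representative stereotactic body radiotherapy (SBRT) schedules.

Every plan starts from the identical pre-treatment tumor (30-day run-in
from the 2 mm^3 seed) and is scored by the treatment ratio — post-course
over pre-course volume, lower is better.
"""

from lungrt import PRESET_GROUPS, compare_plans, get_preset

specs = [get_preset(name) for name in PRESET_GROUPS["sbrt"]]
report = compare_plans(specs, run_in_days=30.0)

cols = ["plan", "total_dose_gy", "dose_per_fraction_gy",
        "ratio_T1", "ratio_active", "ratio_total"]
print(report.frame[cols].to_string(index=False, float_format=lambda x: f"{x:.3g}"))

print("\nall four schedules essentially eradicate the active compartments")
print("(active ratios < 1e-9); the total ratio stays higher because the")
print("non-dividing pool is untouched by radiation and clears only at the")
print("blood-clearance rate. Toxicity is outside this model, so the table")
print("ranks tumor control only.")
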