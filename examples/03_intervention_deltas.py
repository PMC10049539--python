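"""Assess the 28-day L-arginine + vitamin C effect on the metabolite panel.

Builds per-subject changes (day 28 − baseline) from a paired synthetic
cohort at the published effect sizes, classifies active vs placebo with
rDCV PLS-DA, and runs the univariate battery on the deltas and index
log-ratios.
"""
from argmet import (
    AnalysisConfig,
    default_intervention_cohort,
    run_analysis,
)

table = default_intervention_cohort(seed=1)
config = AnalysisConfig(analysis="treatment_vs_placebo_deltas",
                        repetitions=50, permutations=200, seed=1)
report = run_analysis(table, config)

fom = report["figures_of_merit"]
print(f"accuracy {fom['accuracy_mean']:.1f} ± {fom['accuracy_sd']:.1f} %  "
      f"(permutation p = {fom['permutation']['p_value']:.3f})\n")
print(f"{'variable':14s} {'mean diff':>10s} {'effect':>7s}  test            p")
for row in report["univariate"]:
    print(f"{row['variable']:14s} {row['mean_diff']:10.3f} "
          f"{row['effect_size']:7.2f}  {row['test']:13s} {row['p']:.3f}")

print("\nThe arginine delta difference is the treatment signal (generated at")
print("62.5 µM, d ≈ 0.72); the weak multivariate accuracy shows that a")
print("single-analyte effect does not separate the arms on the full panel.")
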