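"""Full backtest across training lengths with Bonferroni-corrected comparisons.

Sweeps 1/2/3-year training windows for several models, reports the MAPE table
(best model flagged per column) and tests whether the per-day absolute
percentage errors of the model pairs differ significantly.
"""

import datetime as dt

import surgecast as sc

_, holidays, streams = sc.scenario_data("CALIBRATED_DEFAULT", seed=1)

models = {
    "ROLLING_WINDOW": sc.RollingWindowConfig(
        tau=3, theta=2, holiday_mode=sc.HolidayMode.HOLIDAY_AWARE
    ),
    "RANDOM_FOREST": sc.EstimatorSpec("RANDOM_FOREST"),
    "ENSEMBLE": sc.EstimatorSpec("ENSEMBLE"),
}

result = sc.run_benchmark(
    {"overall": streams["overall"], "emergency": streams["emergency"]},
    models,
    test_start=dt.date(2019, 1, 1),
    training_years=(1, 2, 3),
    holidays=holidays,
)

print(result.table.pivot_table(index="model", columns=["stream", "training_years"],
                               values="mape").round(2).to_string())

comparisons = sc.compare_models(result.abs_pe_for("overall", 3), alpha=0.05)
print(f"\npaired two-tailed t-tests on daily |PE|, overall stream, 3-year training")
print(f"K = {comparisons[0].k} comparisons, Bonferroni threshold "
      f"{comparisons[0].adjusted_alpha:.3e}")
for c in comparisons:
    verdict = "significant" if c.significant else "not significant"
    print(f"  {c.model_a} vs {c.model_b}: t = {c.t_statistic:+.2f}, "
          f"p = {c.p_value:.3g} ({verdict})")
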