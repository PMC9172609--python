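"""Forecast through a pandemic-style demand shock and watch the error spike.

A forecaster trained on historical patterns cannot anticipate a lockdown: in
the shock scenario demand drops to ~30% of normal for one month, and the
monthly MAPE of the rolling window spikes in exactly that month before
recovering — the qualitative failure mode of any static-history model under
unprecedented conditions.
"""

import datetime as dt

import surgecast as sc
from surgecast.evaluation import (
    BreakdownBy,
    MaskKind,
    apply_mask,
    breakdown,
    build_error_records,
)
from surgecast.io import slice_series

_, holidays, streams = sc.scenario_data("PANDEMIC_SHOCK", seed=1)
overall = streams["overall"]

history = slice_series(overall, dt.date(2016, 1, 1), dt.date(2019, 12, 31))
forecasts = sc.forecast_range(
    history, dt.date(2020, 1, 1), dt.date(2020, 6, 30),
    sc.RollingWindowConfig(tau=3, theta=2, holiday_mode=sc.HolidayMode.HOLIDAY_AWARE),
    holidays,
)

testing = slice_series(overall, dt.date(2020, 1, 1), dt.date(2020, 6, 30))
mask = apply_mask(testing, MaskKind.EMERGENCY_OR_OVERALL, holidays)
records = build_error_records(testing, {f.date: f.point for f in forecasts},
                              mask, holidays)

table = breakdown(records, BreakdownBy.MONTH)
print("monthly MAPE (%) forecasting Jan-Jun 2020 from pre-2020 history")
print("(April is the lockdown month: demand fell to ~30% of normal)")
for _, row in table.iterrows():
    month = dt.date(2020, int(row["group"]), 1).strftime("%B")
    bar = "#" * int(min(row["mape"], 300) // 5)
    print(f"  {month:9s} {row['mape']:7.1f}  {bar}")
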