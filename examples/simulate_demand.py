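"""Generate a synthetic hospital demand scenario and look at its calendar structure.

The generator emulates the daily surgical caseload of a large metropolitan
hospital: ~68 surgeries/day on average, a Friday peak near 95, weekends and
public holidays near 22, and elective surgery absent on non-working days.
"""

import datetime as dt

import surgecast as sc

params, holidays, streams = sc.scenario_data("CALIBRATED_DEFAULT", seed=1)
overall = streams["overall"]

print(f"simulated {overall.start}..{overall.end}: "
      f"{overall.total()} surgeries over {len(overall)} days "
      f"({overall.counts.mean():.1f}/day)")

by_dow = overall.counts.groupby(overall.counts.index.dayofweek).mean()
names = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]
for i, name in enumerate(names):
    print(f"  {name}: {by_dow[i]:5.1f} surgeries/day")

elective = streams["elective"]
weekend_elective = sum(
    elective.count_on(d) for d in elective.dates() if d.weekday() >= 5
)
print(f"elective surgeries on weekends: {weekend_elective} (electives are not "
      f"scheduled on non-working days)")
print(f"public holidays in calendar: {len(holidays)}")
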