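"""Build the supervised design: lags, calendar features, scaling, split.

Each row predicts day t from days t-1..t-6 of admissions and environmental
values (single-day lags plus moving mean/SD) and from calendar features.
Min-max scaling and one-hot category sets are fitted on the chronological
training block (2015-2017) only and applied to the 2018 test block.
"""

from datetime import date

from stackcast import GeneratorConfig, generate_panel, default_holidays
from stackcast import LagSpec, prepare_datasets

panel = generate_panel(GeneratorConfig(seed=42))
holidays = default_holidays(range(2015, 2019), seed=0)
split = prepare_datasets(panel, LagSpec(6), holidays, date(2018, 1, 1))

groups = {}
for col, g in split.groups.items():
    groups.setdefault(g, []).append(col)

print(f"training rows: {len(split.X_train)}   test rows: {len(split.X_test)}")
print(f"feature columns: {split.X_train.shape[1]}")
for g, cols in groups.items():
    print(f"  {g:14s} {len(cols):3d} columns   e.g. {cols[:3]}")
print()
print("88 lag columns = 11 series x (6 single-day lags + moving mean + SD);")
print("the rest are calendar indicators. 1090 training rows are the 1096")
print("calendar days of 2015-2017 minus the first 6, which lack lag history.")
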