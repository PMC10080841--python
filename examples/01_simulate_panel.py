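"""Generate a study-shaped synthetic daily admissions panel and summarise it.

The generator emulates four years (1461 days) of daily cerebrovascular
admission counts for a large city together with ten environmental series
(particulates, gaseous pollutants, an air-quality index, temperature and
humidity): a rising trend, winter-peaked seasonality, weekend and holiday
dips, short-term lagged environmental effects, and overdispersed counts.
"""

from stackcast import GeneratorConfig, generate_panel, panel_summary

config = GeneratorConfig(seed=42)
panel = generate_panel(config)

print(f"panel: {len(panel)} days, {panel['date'].iloc[0].date()} .. "
      f"{panel['date'].iloc[-1].date()}")
print()
print(panel_summary(panel).round(1))
print()
print("The ha_count row is calibrated to the scale of daily cerebrovascular")
print("admissions in a city of several million (mean ~70, SD ~30, minima on")
print("holiday weeks, maxima on polluted winter days).")
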