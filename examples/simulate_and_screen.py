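"""Simulate a two-year GPS dataset and screen it on fix quality.

Builds one bear monitored through a good (2008) and a poor (2009) natural
food year, screens the fixes on PDOP (3D kept at <= 10, 2D at <= 5) plus the
48-h post-release window, and prints how much data each rule removes.
"""

from urbanbear import (BearSpec, SimConfig, assign_seasons, coverage_filter,
                       gen_landscape, gen_tracks, screen_locations)

cfg = SimConfig(seed=1, fix_interval_min=30)
bear = BearSpec("B0", "F", 5, [(2008, "good"), (2009, "poor")])
land = gen_landscape(cfg)
locs, events = gen_tracks(land, [bear], cfg)

screened, report = screen_locations(locs, events)
print(f"fixes simulated : {report.n_input}")
print(f"fixes retained  : {report.n_retained}  "
      f"({100 * report.fraction_removed:.1f}% removed)")
print(report.per_bear.to_string(index=False))

eligible = coverage_filter(assign_seasons(screened))
print("\nbear-season eligibility (>= 90% of the season spanned):")
print(eligible.to_string(index=False))
# The removed fraction sits near 11%: the PDOP mixture is calibrated to the
# screening loss a field GPS-collar study typically reports.
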