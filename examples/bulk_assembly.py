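"""Simulate a bulk pyrene polymerization assay and extract its
kinetic descriptors, including the filament-end concentration series.

2 µM actin assembles by spontaneous (trimeric) nucleation and
barbed-end elongation (k_on 10.3 µM⁻¹s⁻¹, k_off 1.4 s⁻¹).  The
normalized fluorescence trace is reduced to the bulk polymerization
rate (slope at half-max), the lag time (5% threshold), and inverted
into filament-end concentrations, which are compared against the
simulator's ground truth.
"""

import numpy as np

from actokin import (
    BARBED_END,
    BulkCondition,
    bulk_polymerization_rate,
    filament_end_series,
    lag_time,
    peak_end_concentration,
    simulate_spontaneous_assembly,
)

res = simulate_spontaneous_assembly(BulkCondition(a_total=2.0), t_end=2000.0)
trace = res.trace

rate = bulk_polymerization_rate(trace)
t_lag = lag_time(trace)
series = filament_end_series(trace, BARBED_END, a_total=2.0)
peak = peak_end_concentration(series, trace)

print(f"bulk polymerization rate : {rate.slope:.2e} s^-1 "
      f"(fit window {rate.window[0]:.0f}-{rate.window[1]:.0f} s)")
print(f"lag time (5% threshold)  : {t_lag:.0f} s")
print(f"ends at half-max         : {peak.at_half_max*1e3:.2f} nM")
print(f"peak end concentration   : {peak.maximum*1e3:.2f} nM")

sel = (trace.f > 0.05) & (trace.f < 0.90) & series.valid_mask
err = np.max(np.abs(series.ends[sel] - res.ends[sel]) / res.ends[sel])
print(f"inversion vs ground truth: max {err*100:.1f}% relative error "
      "(0.05 < F_norm < 0.90)")
# The inversion turns the signal slope (polymer flux) into the number
# of growing ends; a few nM of ends polymerize 2 µM actin in ~10 min.
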