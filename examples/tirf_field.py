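"""Simulate a TIRF filament field and estimate nucleation and
elongation rates.

Filaments appear by Poisson nucleation (5.1e-6 µm⁻² s⁻¹) and grow
linearly (28.1 ± 4.5 nm/s).  The filament-density time course gives
the apparent nucleation rate k_nuc by linear regression over its
region of linear increase; per-filament length-vs-time fits give the
elongation rate, convertible to subunits/s via the 2.73 nm helical
rise.
"""

from actokin import (
    density_timecourse,
    estimate_nucleation_rate,
    nm_per_s_to_subunits,
    simulate_field,
    track_elongation,
)

field = simulate_field(
    area=6400.0, duration=600.0, k_nuc_true=5.1e-6,
    v_mean=28.1, v_sd=4.5, length_noise_sd=20.0, frame_dt=5.0, seed=42,
)
t, density = density_timecourse(field)
nuc = estimate_nucleation_rate(t, density)
elo = track_elongation(field)

print(f"filaments detected : {len(field.filaments)}")
print(f"k_nuc estimate     : {nuc.k_nuc:.2e} um^-2 s^-1 "
      f"(truth 5.1e-06, R^2 = {nuc.r_squared:.3f})")
print(f"elongation rate    : {elo.mean:.1f} +/- {elo.sd:.1f} nm/s "
      f"({len(elo.per_filament_rates)} filaments)")
print(f"subunit addition   : {elo.subunit_rate:.1f} subunits/s")
# ~10.3 subunits/s at 1 µM actin reproduces the apparent barbed-end
# association rate constant of 10.3 µM⁻¹s⁻¹.
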