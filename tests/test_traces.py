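"""Descriptor extraction and the filament-end inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actokin import (
    BARBED_END,
    BulkCondition,
    FluorescenceTrace,
    NucleationParams,
    RateConstants,
    bulk_polymerization_rate,
    filament_end_series,
    fit_monoexponential,
    lag_time,
    normalize_trace,
    peak_end_concentration,
    pointed_elongation_rate,
    simulate_dilution_depolymerization,
    simulate_pointed_elongation,
    simulate_spontaneous_assembly,
)
from actokin.traces import NoAssemblyError, TraceAnalysisError


def make_trace(t, f, normalized=False):
    return FluorescenceTrace(np.asarray(t, float), np.asarray(f, float),
                             normalized=normalized)


class TestNormalize:
    @settings(deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=1e-3, max_value=1e3),
        b=st.floats(min_value=-1e3, max_value=1e3),
    )
    def test_affine_invariance(self, a, b):
        """normalize(a·F + b) == normalize(F) for any a > 0."""
        t = np.linspace(0, 100, 50)
        f = 1.0 / (1.0 + np.exp(-(t - 50) / 8.0))
        base = normalize_trace(make_trace(t, f))
        scaled = normalize_trace(make_trace(t, a * f + b))
        assert np.allclose(base.f, scaled.f, atol=1e-9)

    def test_identity_on_flat_tailed_trace(self):
        """A trace whose first/last 5% sit exactly at 0/1 is unchanged."""
        t = np.linspace(0, 100, 200)
        f = np.clip((t - 20) / 50.0, 0.0, 1.0)  # flat head and plateau
        out = normalize_trace(make_trace(t, f))
        assert np.max(np.abs(out.f - f)) < 1e-6

    def test_decreasing_trace_raises(self):
        t = np.linspace(0, 100, 50)
        with pytest.raises(NoAssemblyError):
            normalize_trace(make_trace(t, 1.0 - t / 100.0))

    def test_short_trace_rejected(self):
        with pytest.raises(TraceAnalysisError):
            normalize_trace(make_trace([0, 1, 2, 3], [0, 1, 2, 3]))


class TestBulkRate:
    def test_exact_ramp_slope(self):
        t = np.linspace(0, 2000, 400)
        f = np.minimum(1.0, t / 1000.0)
        fit = bulk_polymerization_rate(make_trace(t, f, normalized=True))
        assert fit.slope == pytest.approx(1e-3, rel=1e-9)
        assert fit.window[0] >= 300 and fit.window[1] <= 700

    def test_sparse_trace_widens_band_deterministically(self):
        t = np.linspace(0, 10, 21)
        f = np.minimum(1.0, t / 5.0)  # only 3 points inside [0.35, 0.65]
        fit1 = bulk_polymerization_rate(make_trace(t, f, normalized=True))
        fit2 = bulk_polymerization_rate(make_trace(t, f, normalized=True))
        assert fit1.n_points >= 5
        assert fit1 == fit2

    def test_never_crossing_half_max_raises(self):
        t = np.linspace(0, 100, 30)
        with pytest.raises(TraceAnalysisError):
            bulk_polymerization_rate(make_trace(t, 0.3 * t / 100, normalized=True))

    def test_faster_nucleation_gives_larger_slope(
        self, default_assembly, fast_assembly
    ):
        s1 = bulk_polymerization_rate(default_assembly.trace).slope
        s2 = bulk_polymerization_rate(fast_assembly.trace).slope
        assert s2 > s1


class TestLagTime:
    def test_closed_form_ramp(self):
        t = np.linspace(0, 1000, 500)
        assert lag_time(make_trace(t, t / 1000.0, normalized=True)) == pytest.approx(
            50.0, abs=1e-9
        )

    def test_dead_time_shift_equivariance(self):
        t = np.linspace(0, 1000, 501)
        f = np.clip(t / 1000.0, 0, 1)
        base = lag_time(make_trace(t, f, normalized=True))
        # prepend 100 s of zeros (same 2 s sampling)
        t_pre = np.arange(-100, 0, 2.0)
        t2 = np.concatenate([t_pre, t]) + 100.0
        f2 = np.concatenate([np.zeros_like(t_pre), f])
        shifted = lag_time(make_trace(t2, f2, normalized=True))
        assert shifted == pytest.approx(base + 100.0, abs=1e-9)

    def test_lag_decreases_with_nucleation_rate(
        self, default_assembly, fast_assembly
    ):
        assert lag_time(fast_assembly.trace) < lag_time(default_assembly.trace)

    def test_never_reaching_threshold_raises(self):
        t = np.linspace(0, 10, 30)
        with pytest.raises(TraceAnalysisError):
            lag_time(make_trace(t, np.full_like(t, 0.01), normalized=True))


class TestFilamentEndInversion:
    RATES = BARBED_END

    def test_hand_computed_point(self):
        """F = 0.5, dF/dt = 0.01 s⁻¹, 2 µM actin → 1.94 nM ends.

        A linear trace has an exact Savitzky–Golay derivative, so the
        sample at F = 0.5 evaluates the inversion at that exact point:
        numerator 0.01·(2 − 0.13592), denominator
        10.3·(2·0.5 + 0.13592·0.5) − 1.4 = 9.600 s⁻¹.
        """
        t = np.linspace(0, 100, 101)  # dt = 1 s
        f = 0.5 + 0.01 * (t - 50.0)
        series = filament_end_series(make_trace(t, f, normalized=True),
                                     self.RATES, a_total=2.0)
        i = 50
        assert f[i] == 0.5
        assert series.valid_mask[i]
        assert series.ends[i] == pytest.approx(1.9417e-3, rel=1e-3)

    def test_flat_trace_gives_zero_ends(self):
        t = np.linspace(0, 100, 101)
        series = filament_end_series(
            make_trace(t, np.zeros_like(t), normalized=True), self.RATES, 2.0
        )
        assert np.all(series.ends == 0.0)
        assert np.all(series.valid_mask)

    def test_round_trip_recovers_ground_truth_within_10pct(self, default_assembly):
        res = default_assembly
        series = filament_end_series(res.trace, self.RATES, a_total=2.0)
        sel = (res.trace.f > 0.05) & (res.trace.f < 0.90) & series.valid_mask
        assert np.count_nonzero(sel) > 20
        rel = np.abs(series.ends[sel] - res.ends[sel]) / res.ends[sel]
        assert np.max(rel) < 0.10

    def test_plateau_points_are_masked(self, default_assembly):
        series = filament_end_series(default_assembly.trace, self.RATES, 2.0)
        assert not np.any(series.valid_mask[default_assembly.trace.f > 0.96])

    def test_subcritical_total_actin_rejected(self):
        t = np.linspace(0, 100, 101)
        with pytest.raises(ValueError):
            filament_end_series(
                make_trace(t, t / 100, normalized=True), self.RATES, a_total=0.1
            )


class TestPeakEnds:
    def test_constant_end_simulation_recovered_at_half_max(self):
        """Seeded growth (no nucleation) has constant N(t); the inversion
        evaluated at half-max must return that constant."""
        n0 = 0.002
        cond = BulkCondition(a_total=2.0, seed_ends=n0, g0=2.0)
        res = simulate_spontaneous_assembly(
            cond, nuc=NucleationParams(k_nuc_base=0.0), t_end=600, n_points=400
        )
        series = filament_end_series(res.trace, BARBED_END, 2.0)
        peak = peak_end_concentration(series, res.trace)
        assert peak.at_half_max == pytest.approx(n0, rel=0.05)

    def test_more_nucleation_gives_higher_peak(
        self, default_assembly, fast_assembly
    ):
        p1 = peak_end_concentration(
            filament_end_series(default_assembly.trace, BARBED_END, 2.0),
            default_assembly.trace,
        )
        p2 = peak_end_concentration(
            filament_end_series(fast_assembly.trace, BARBED_END, 2.0),
            fast_assembly.trace,
        )
        assert p2.maximum > p1.maximum
        assert p2.at_half_max > p1.at_half_max

    def test_all_masked_series_raises(self):
        t = np.linspace(0, 100, 101)
        f = np.full_like(t, 0.99)  # everything beyond the plateau mask
        series = filament_end_series(make_trace(t, f, normalized=True),
                                     BARBED_END, 2.0)
        with pytest.raises(TraceAnalysisError):
            peak_end_concentration(series, make_trace(t, f, normalized=True))


class TestMonoExponential:
    def test_exact_exponential_recovered_to_6_digits(self):
        t = np.linspace(0, 500, 200)
        tr = make_trace(t, 0.2 + 0.8 * np.exp(-0.01 * t))
        fit = fit_monoexponential(tr)
        assert fit.k_app == pytest.approx(0.01, rel=1e-6)
        assert fit.amplitude == pytest.approx(0.8, rel=1e-6)
        assert not fit.degenerate

    def test_noisy_recovery_within_5pct(self):
        tr = simulate_dilution_depolymerization(
            f0=1.0, k_dep0=0.01, noise_sd=0.02, seed=11
        )
        assert fit_monoexponential(tr).k_app == pytest.approx(0.01, rel=0.05)

    def test_rising_exponential_supported(self):
        t = np.linspace(0, 300, 100)
        tr = make_trace(t, 1.0 - np.exp(-0.02 * t))
        fit = fit_monoexponential(tr)
        assert fit.k_app == pytest.approx(0.02, rel=1e-5)
        assert fit.amplitude == pytest.approx(-1.0, rel=1e-5)

    def test_constant_trace_flagged_degenerate(self):
        t = np.linspace(0, 100, 50)
        fit = fit_monoexponential(make_trace(t, np.full_like(t, 3.7)))
        assert fit.degenerate
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)


class TestPointedElongationRate:
    def test_pure_ramp_slope_exact(self):
        t = np.linspace(0, 100, 60)
        fit = pointed_elongation_rate(make_trace(t, 0.02 * t))
        assert fit.slope == pytest.approx(0.02, rel=1e-9)

    def test_capper_slope_ratio_matches_occupancy(self):
        """ratio capper/no-capper = 1 − block_fraction·θ within 3%."""
        from actokin import CapperParams, capper_occupancy

        capper = CapperParams("c", kd_pe=0.085, block_fraction=1.0)
        # record only the initial phase, as the seeded assay does
        free = simulate_pointed_elongation(
            seed_ends=0.002, g0=2.0, t_end=120.0, n_points=300
        )
        for conc in (0.03, 0.085, 0.3):
            capped = simulate_pointed_elongation(
                seed_ends=0.002, g0=2.0, capper=capper, capper_conc=conc,
                t_end=120.0, n_points=300,
            )
            ratio = (
                pointed_elongation_rate(capped).slope
                / pointed_elongation_rate(free).slope
            )
            expected = 1.0 - capper_occupancy(conc, 0.085)
            assert ratio == pytest.approx(expected, rel=0.03)

    def test_decaying_trace_raises_degenerate_slope(self):
        t = np.linspace(0, 100, 60)
        with pytest.raises(TraceAnalysisError, match="does not rise"):
            pointed_elongation_rate(make_trace(t, np.exp(-0.05 * t)))

    def test_too_few_initial_points_raises(self):
        t = np.linspace(0, 100, 30)
        f = 1.0 - np.exp(-0.5 * t)  # rises past 15% within ~1 sample
        with pytest.raises(TraceAnalysisError, match="initial linear phase"):
            pointed_elongation_rate(make_trace(t, f))
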