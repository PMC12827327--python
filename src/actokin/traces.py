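"""Kinetic descriptors extracted from pyrene fluorescence traces.

The bulk pyrene assay reports polymer mass as a fluorescence increase.
From a normalized trace this module extracts the descriptors used to
characterize assembly kinetics: the bulk polymerization rate (slope of
the linear region around half-maximal signal), the lag time (5% of the
final signal), apparent mono-exponential rate constants (dilution
depolymerization, nucleotide exchange), initial pointed-end elongation
rates, and — the centerpiece — the inversion of the normalized trace
into a filament-end concentration time course:

    [ends](t) = (dF/dt · (A − cc)) / (k_on·(A·(1−F) + cc·F) − k_off)

with A the total actin concentration and cc = k_off/k_on the barbed-end
critical concentration.  The numerator converts signal slope into a
polymerization flux (µM/s); the denominator is the per-end net subunit
addition rate (s⁻¹) at the free-monomer concentration implied by F.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .model import FluorescenceTrace, RateConstants

__all__ = [
    "TraceAnalysisError",
    "NoAssemblyError",
    "FitFailureError",
    "EndConcentrationSeries",
    "KineticDescriptors",
    "LinearFit",
    "MonoExpFit",
    "PeakEnds",
    "normalize_trace",
    "bulk_polymerization_rate",
    "lag_time",
    "filament_end_series",
    "peak_end_concentration",
    "fit_monoexponential",
    "pointed_elongation_rate",
    "bulk_descriptors",
]


class TraceAnalysisError(ValueError):
    """A trace does not support the requested descriptor."""


class NoAssemblyError(TraceAnalysisError):
    """The signal never rises above its baseline."""


class FitFailureError(TraceAnalysisError):
    """A nonlinear fit failed to converge after restarts."""


@dataclass
class EndConcentrationSeries:
    """Filament-end concentration inverted from a normalized trace.

    Points where the inversion is ill-conditioned (signal near plateau,
    or the per-end rate denominator near its zero at F → 1) carry
    ``valid_mask == False``.
    """

    t: np.ndarray
    ends: np.ndarray  # µM; >= 0 wherever valid
    valid_mask: np.ndarray


@dataclass
class KineticDescriptors:
    """Scalar summaries of one bulk polymerization trace."""

    bulk_rate: float  # normalized-signal slope at half-max, s⁻¹
    t_lag: float  # s
    k_app: Optional[float] = None  # mono-exponential rate constant, s⁻¹
    elong_rate_initial: Optional[float] = None  # a.u. s⁻¹


@dataclass
class LinearFit:
    slope: float
    intercept: float
    window: tuple[float, float]  # time window of the fit, s
    n_points: int


@dataclass
class MonoExpFit:
    """F(t) = offset + amplitude · exp(−k_app·t)."""

    k_app: float
    amplitude: float
    offset: float
    degenerate: bool = False


@dataclass
class PeakEnds:
    at_half_max: float  # ends at the time F_norm crosses 0.5, µM
    maximum: float  # global max over the valid mask, µM


def normalize_trace(
    trace: FluorescenceTrace, edge_fraction: float = 0.05
) -> FluorescenceTrace:
    """Rescale a raw trace to F_norm = (F − F_min)/(F_plateau − F_min).

    F_min is the mean of the first ``edge_fraction`` of points and
    F_plateau the mean of the last ``edge_fraction``; the trace must
    show a net signal increase (plateau above baseline).
    """
    if len(trace) < 20:
        raise TraceAnalysisError("normalization needs at least 20 points")
    k = max(1, int(round(edge_fraction * len(trace))))
    f_min = float(np.mean(trace.f[:k]))
    f_plat = float(np.mean(trace.f[-k:]))
    if f_plat <= f_min:
        raise NoAssemblyError(
            f"no signal increase: plateau {f_plat:.4g} <= baseline {f_min:.4g}"
        )
    f_norm = (trace.f - f_min) / (f_plat - f_min)
    return FluorescenceTrace(
        trace.t.copy(), f_norm, normalized=True, condition=trace.condition
    )


def _least_squares_line(t: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, f, 1)
    return float(slope), float(intercept)


def bulk_polymerization_rate(
    trace: FluorescenceTrace,
    band: tuple[float, float] = (0.35, 0.65),
    min_points: int = 5,
) -> LinearFit:
    """Slope of the linear region around half-maximal fluorescence.

    Fits all points with F_norm inside ``band``; if fewer than
    ``min_points`` fall inside, the band is widened symmetrically in
    0.05 steps until enough do (deterministic fallback for sparse
    traces).
    """
    if not trace.normalized:
        raise TraceAnalysisError("bulk rate requires a normalized trace")
    if np.max(trace.f) < 0.5:
        raise TraceAnalysisError("trace never reaches half-maximal signal")
    lo, hi = band
    while True:
        sel = (trace.f >= lo) & (trace.f <= hi)
        if np.count_nonzero(sel) >= min_points:
            break
        lo -= 0.05
        hi += 0.05
        if lo <= -1.0:  # pragma: no cover - guarded by the 0.5 check
            raise TraceAnalysisError("could not assemble a half-max fit window")
    slope, intercept = _least_squares_line(trace.t[sel], trace.f[sel])
    return LinearFit(
        slope=slope,
        intercept=intercept,
        window=(float(trace.t[sel][0]), float(trace.t[sel][-1])),
        n_points=int(np.count_nonzero(sel)),
    )


def lag_time(trace: FluorescenceTrace, threshold: float = 0.05) -> float:
    """Time at which the trace first reaches 5% of its final signal.

    Linearly interpolated between the bracketing samples.
    """
    if not trace.normalized:
        raise TraceAnalysisError("lag time requires a normalized trace")
    f = trace.f
    if f[0] >= threshold:
        return float(trace.t[0])
    above = np.nonzero(f >= threshold)[0]
    if len(above) == 0:
        raise TraceAnalysisError(f"trace never reaches F_norm = {threshold}")
    i = above[0]
    t0, t1 = trace.t[i - 1], trace.t[i]
    f0, f1 = f[i - 1], f[i]
    return float(t0 + (threshold - f0) / (f1 - f0) * (t1 - t0))


def filament_end_series(
    trace: FluorescenceTrace,
    rates: RateConstants,
    a_total: float,
    savgol_window: int = 11,
    savgol_order: int = 2,
    plateau_mask: float = 0.95,
    denominator_floor: float = 1e-3,
) -> EndConcentrationSeries:
    """Invert a normalized trace into a filament-end concentration series.

    dF/dt is estimated by a Savitzky–Golay derivative (default window 11
    points, polynomial order 2); sampling must be uniform.  Points with
    F_norm above ``plateau_mask`` or with the per-end rate denominator
    below ``denominator_floor · (k_on·a_total − k_off)`` are masked
    invalid (the equation degenerates to 0/0 as F → 1).  Valid end
    concentrations are floored at 0 (derivative noise can make the raw
    estimate slightly negative).
    """
    if not trace.normalized:
        raise TraceAnalysisError("the inversion requires a normalized trace")
    cc = rates.cc
    if a_total <= cc:
        raise ValueError("a_total must exceed the critical concentration")
    dt = np.diff(trace.t)
    dt0 = float(np.median(dt))
    # tolerate rounding-level jitter (e.g. from CSV round-trips)
    if not np.allclose(dt, dt0, rtol=1e-3, atol=1e-9):
        raise ValueError("filament_end_series requires uniform time sampling")
    window = min(savgol_window, len(trace) if len(trace) % 2 else len(trace) - 1)
    if window <= savgol_order:
        raise TraceAnalysisError("trace too short for the derivative filter")
    dfdt = savgol_filter(
        trace.f, window_length=window, polyorder=savgol_order,
        deriv=1, delta=dt0,
    )
    f = trace.f
    denom = rates.k_on * (a_total * (1.0 - f) + cc * f) - rates.k_off
    floor = denominator_floor * (rates.k_on * a_total - rates.k_off)
    valid = (f <= plateau_mask) & (denom >= floor)
    ends = np.zeros_like(f)
    ends[valid] = dfdt[valid] * (a_total - cc) / denom[valid]
    ends = np.maximum(ends, 0.0)
    return EndConcentrationSeries(t=trace.t.copy(), ends=ends, valid_mask=valid)


def peak_end_concentration(
    series: EndConcentrationSeries, trace: FluorescenceTrace
) -> PeakEnds:
    """End concentration at half-maximal polymerization, plus the maximum.

    The half-max value is the series interpolated at the time F_norm
    first crosses 0.5; the maximum is taken over the valid mask.
    """
    if not np.any(series.valid_mask):
        raise TraceAnalysisError("all points of the end series are masked")
    if np.max(trace.f) < 0.5:
        raise TraceAnalysisError("trace never reaches half-maximal signal")
    above = np.nonzero(trace.f >= 0.5)[0]
    i = above[0]
    if i == 0:
        t_half = float(trace.t[0])
    else:
        t0, t1 = trace.t[i - 1], trace.t[i]
        f0, f1 = trace.f[i - 1], trace.f[i]
        t_half = float(t0 + (0.5 - f0) / (f1 - f0) * (t1 - t0))
    tv = series.t[series.valid_mask]
    ev = series.ends[series.valid_mask]
    at_half = float(np.interp(t_half, tv, ev))
    return PeakEnds(at_half_max=at_half, maximum=float(np.max(ev)))


def fit_monoexponential(trace: FluorescenceTrace) -> MonoExpFit:
    """Least-squares fit of F(t) = offset + amplitude·exp(−k_app·t).

    Initial guesses come from a log-linearized tail; k_app is bounded
    positive.  A trace with vanishing amplitude is returned with the
    ``degenerate`` flag set instead of reporting a spurious rate.
    """
    if len(trace) < 10:
        raise TraceAnalysisError("mono-exponential fit needs >= 10 points")
    t, f = trace.t, trace.f
    span = float(np.max(f) - np.min(f))
    scale = max(abs(float(np.max(f))), abs(float(np.min(f))), 1e-30)
    if span < 1e-9 * scale:
        return MonoExpFit(k_app=0.0, amplitude=0.0, offset=float(np.mean(f)),
                          degenerate=True)
    k_tail = max(1, len(f) // 10)
    offset0 = float(np.mean(f[-k_tail:]))
    amp0 = float(f[0] - offset0)
    # log-linearize |f - offset| on the early half for a rate guess
    resid = np.abs(f - offset0)
    sel = resid > 1e-3 * max(abs(amp0), span)
    if np.count_nonzero(sel) >= 3:
        k0_guess, _ = _least_squares_line(t[sel], np.log(resid[sel]))
        k0_guess = max(-k0_guess, 1e-6)
    else:
        k0_guess = 3.0 / (t[-1] - t[0])

    def model(tt, k, a, c):
        return c + a * np.exp(-k * tt)

    t_span = t[-1] - t[0]
    for k0 in [k0_guess, 1.0 / t_span, 10.0 / t_span, 100.0 / t_span]:
        try:
            popt, _ = curve_fit(
                model, t, f, p0=[k0, amp0, offset0],
                bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        k_app, amp, offset = (float(v) for v in popt)
        degenerate = abs(amp) < 1e-6 * max(scale, 1e-30)
        return MonoExpFit(k_app=k_app, amplitude=amp, offset=offset,
                          degenerate=degenerate)
    raise FitFailureError("mono-exponential fit did not converge")


def pointed_elongation_rate(
    trace: FluorescenceTrace,
    rise_fraction: float = 0.15,
    min_points: int = 8,
) -> LinearFit:
    """Initial slope of a raw seeded pointed-end elongation trace.

    Fits the initial window in which the signal has risen at most
    ``rise_fraction`` of the total amplitude above its starting value.
    """
    f, t = trace.f, trace.t
    amplitude = float(np.max(f) - f[0])
    if amplitude <= 0:
        raise TraceAnalysisError(
            "degenerate slope: signal does not rise above its start "
            "(is this an elongation trace?)"
        )
    limit = f[0] + rise_fraction * amplitude
    beyond = np.nonzero(f > limit)[0]
    n = int(beyond[0]) if len(beyond) else len(f)
    if n < min_points:
        raise TraceAnalysisError(
            f"only {n} points in the initial linear phase (< {min_points})"
        )
    slope, intercept = _least_squares_line(t[:n], f[:n])
    return LinearFit(
        slope=slope, intercept=intercept,
        window=(float(t[0]), float(t[n - 1])), n_points=n,
    )


def bulk_descriptors(trace: FluorescenceTrace) -> KineticDescriptors:
    """Convenience bundle: bulk rate and lag time of a normalized trace."""
    return KineticDescriptors(
        bulk_rate=bulk_polymerization_rate(trace).slope,
        t_lag=lag_time(trace),
    )
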