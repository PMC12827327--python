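"""Titration-level binding analysis for pointed-end cappers.

Per-concentration kinetic rates (initial pointed-end elongation rates,
or apparent depolymerization rate constants) are normalized to the
capper-free control and fitted with the hyperbolic binding isotherm

    y = y0 + (ymax − y0) · xⁿ / (Kⁿ + xⁿ),   y0 = 1, n = 1

whose half-saturation constant K is reported as the apparent K_D
(elongation inhibition) or K_50% (depolymerization protection).  ymax
is the residual activity at capper saturation: 0 for a full cap, > 0
for partial protection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .model import FluorescenceTrace
from .traces import (
    FitFailureError,
    TraceAnalysisError,
    fit_monoexponential,
    pointed_elongation_rate,
)

__all__ = [
    "MissingControlError",
    "UnresolvableFitError",
    "TitrationSeries",
    "HyperbolicFit",
    "TitrationReport",
    "hyperbolic",
    "normalize_to_control",
    "fit_hyperbolic",
    "titration_pipeline",
]


class MissingControlError(ValueError):
    """No capper-free (0-concentration) control in the titration."""


class UnresolvableFitError(ValueError):
    """The data carry no concentration dependence; K is not identifiable."""


@dataclass
class TitrationSeries:
    """Normalized rates y(conc) with y(0) = 1 by construction."""

    conc: np.ndarray  # µM, distinct, includes 0
    y: np.ndarray  # dimensionless
    replicate_sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.replicate_sd is not None:
            self.replicate_sd = np.asarray(self.replicate_sd, dtype=float)
        if len(np.unique(self.conc)) != len(self.conc):
            raise ValueError("concentrations must be distinct after averaging")


@dataclass
class HyperbolicFit:
    """Fitted hyperbolic isotherm parameters."""

    k_half: float  # µM (apparent K_D or K_50%)
    y0: float
    ymax: float
    n: float
    sd_k_half: float  # bootstrap SD, µM (nan if bootstrap disabled)
    residual_rms: float
    warnings: list[str] = field(default_factory=list)

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return hyperbolic(x, self.k_half, self.ymax, self.y0, self.n)


def hyperbolic(
    x: np.ndarray | float, k: float, ymax: float, y0: float = 1.0, n: float = 1.0
) -> np.ndarray | float:
    """y = y0 + (ymax − y0)·xⁿ/(Kⁿ + xⁿ)."""
    xn = np.asarray(x, dtype=float) ** n
    return y0 + (ymax - y0) * xn / (k**n + xn)


def normalize_to_control(
    conc: Sequence[float], rates: Sequence[float]
) -> TitrationSeries:
    """Average replicates per concentration and divide by the 0-control.

    ``conc``/``rates`` may contain repeated concentrations (replicates);
    they are averaged first and the replicate SD is propagated through
    the division by the control mean (first-order, including the
    control's own uncertainty).
    """
    conc = np.asarray(conc, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if conc.shape != rates.shape:
        raise ValueError("conc and rates must have the same length")
    if not np.any(conc == 0.0):
        raise MissingControlError("titration lacks a 0-concentration control")
    uniq = np.unique(conc)
    means = np.array([np.mean(rates[conc == c]) for c in uniq])
    counts = np.array([np.count_nonzero(conc == c) for c in uniq])
    sds = np.array(
        [
            np.std(rates[conc == c], ddof=1) if np.count_nonzero(conc == c) > 1 else 0.0
            for c in uniq
        ]
    )
    r0 = means[uniq == 0.0][0]
    if r0 <= 0:
        raise ValueError("control rate must be > 0 for normalization")
    y = means / r0
    sd0 = sds[uniq == 0.0][0]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt(
            np.where(means != 0, (sds / np.where(means != 0, means, 1.0)) ** 2, 0.0)
            + (sd0 / r0) ** 2
        )
    sd_y = np.abs(y) * rel
    if not np.any(counts > 1):
        sd_y = None
    return TitrationSeries(conc=uniq, y=y, replicate_sd=sd_y)


def fit_hyperbolic(
    series: TitrationSeries,
    fix_y0: float = 1.0,
    fix_n: float = 1.0,
    ymax_free: bool = True,
    n_bootstrap: int = 1000,
    seed: Optional[int] = None,
    weighted: bool = False,
) -> HyperbolicFit:
    """Least-squares fit of the hyperbolic isotherm.

    y0 and the Hill coefficient are fixed (defaults 1 and 1); K and —
    unless ``ymax_free`` is False, in which case ymax is pinned to 0
    (full block) — ymax are fitted.  With ``weighted=True`` inverse-
    variance weights are taken from ``series.replicate_sd``; this is
    off by default because SDs estimated from the usual 3 replicates
    are noisy enough to bias K noticeably.  ``sd_k_half`` is a
    nonparametric bootstrap SD over concentration points
    (``n_bootstrap`` resamples, seeded); pass ``n_bootstrap=0`` to skip.
    """
    x, y = series.conc, series.y
    if len(x) < 3:
        raise ValueError("need at least 3 concentrations to fit")
    if float(np.ptp(y)) < 1e-12:
        raise UnresolvableFitError(
            "rates show no concentration dependence; K cannot be resolved"
        )
    warnings: list[str] = []
    sigma = None
    if weighted and series.replicate_sd is not None and np.all(series.replicate_sd > 0):
        sigma = series.replicate_sd

    def fit_once(xx: np.ndarray, yy: np.ndarray, ss) -> tuple[float, float]:
        ymax_guess = float(np.clip(yy[np.argmax(xx)], 0.0, fix_y0)) if ymax_free else 0.0
        half_level = (fix_y0 + ymax_guess) / 2.0
        pos = xx[xx > 0]
        k_guess = float(pos[np.argmin(np.abs(yy[xx > 0] - half_level))]) if len(pos) else 1.0
        k_guess = max(k_guess, 1e-6)
        if ymax_free:
            popt, _ = curve_fit(
                lambda t, k, ym: hyperbolic(t, k, ym, fix_y0, fix_n),
                xx, yy, p0=[k_guess, ymax_guess],
                sigma=ss, absolute_sigma=False,
                bounds=([1e-12, 0.0], [np.inf, max(fix_y0, float(np.max(yy)))]),
                maxfev=20000,
            )
            return float(popt[0]), float(popt[1])
        popt, _ = curve_fit(
            lambda t, k: hyperbolic(t, k, 0.0, fix_y0, fix_n),
            xx, yy, p0=[k_guess], sigma=ss, absolute_sigma=False,
            bounds=([1e-12], [np.inf]), maxfev=20000,
        )
        return float(popt[0]), 0.0

    try:
        k_half, ymax = fit_once(x, y, sigma)
    except RuntimeError as exc:
        raise FitFailureError(f"hyperbolic fit did not converge: {exc}") from exc

    resid = y - hyperbolic(x, k_half, ymax, fix_y0, fix_n)
    rms = float(np.sqrt(np.mean(resid**2)))

    pos = np.sort(x[x > 0])
    if len(pos) < 4 or pos[0] > k_half / 3 or pos[-1] < 3 * k_half:
        warnings.append(
            "concentrations do not span [K/3, 3K]; the fit may be ill-posed"
        )

    sd_k = float("nan")
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        ks = []
        npts = len(x)
        for _ in range(n_bootstrap):
            idx = rng.integers(0, npts, size=npts)
            xx, yy = x[idx], y[idx]
            if float(np.ptp(yy)) < 1e-12 or len(np.unique(xx[xx > 0])) < 2:
                continue
            ss = sigma[idx] if sigma is not None else None
            try:
                kb, _ = fit_once(xx, yy, ss)
            except RuntimeError:
                continue
            ks.append(kb)
        if len(ks) >= max(10, n_bootstrap // 10):
            sd_k = float(np.std(ks, ddof=1))
        else:
            warnings.append("bootstrap produced too few successful refits")

    return HyperbolicFit(
        k_half=k_half, y0=fix_y0, ymax=ymax, n=fix_n,
        sd_k_half=sd_k, residual_rms=rms, warnings=warnings,
    )


@dataclass
class TitrationReport:
    """Full provenance of a titration analysis."""

    fit: HyperbolicFit
    series: TitrationSeries
    per_trace: list[dict]
    mode: str


def titration_pipeline(
    traces: Sequence[tuple[float, FluorescenceTrace]],
    mode: Literal["elongation", "depolymerization"],
    n_bootstrap: int = 1000,
    seed: Optional[int] = None,
    ymax_free: bool = True,
) -> TitrationReport:
    """Reduce per-concentration traces to rates, normalize, and fit.

    ``mode='elongation'`` reduces each trace to its initial linear
    slope; ``mode='depolymerization'`` to the apparent mono-exponential
    rate constant.  Errors in any stage are re-raised annotated with the
    offending capper concentration.
    """
    if mode not in ("elongation", "depolymerization"):
        raise ValueError(f"unknown mode {mode!r}")
    concs: list[float] = []
    rates: list[float] = []
    per_trace: list[dict] = []
    for conc, trace in traces:
        try:
            if mode == "elongation":
                lin = pointed_elongation_rate(trace)
                rate = lin.slope
                info = {"conc": conc, "rate": rate, "window": lin.window,
                        "n_points": lin.n_points}
            else:
                exp = fit_monoexponential(trace)
                if exp.degenerate:
                    raise TraceAnalysisError("degenerate (flat) decay trace")
                rate = exp.k_app
                info = {"conc": conc, "rate": rate,
                        "amplitude": exp.amplitude, "offset": exp.offset}
        except TraceAnalysisError as exc:
            raise TraceAnalysisError(
                f"trace at capper concentration {conc} µM: {exc}"
            ) from exc
        concs.append(conc)
        rates.append(rate)
        per_trace.append(info)
    series = normalize_to_control(concs, rates)
    fit = fit_hyperbolic(
        series, n_bootstrap=n_bootstrap, seed=seed, ymax_free=ymax_free
    )
    return TitrationReport(fit=fit, series=series, per_trace=per_trace, mode=mode)
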