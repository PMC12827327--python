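"""Kinetic models of actin filament nucleation and elongation.

Actin assembly is a two-step process: a kinetically unfavourable
nucleation step (formation of a trimeric nucleus) followed by fast,
asymmetric elongation of the nucleus into a filament.  This module
implements that scheme twice — as a deterministic mass-action ODE and as
an exact stochastic simulation (Gillespie SSA) over discrete molecule
counts — together with reduced models for the two seeded pointed-end
assays: elongation from barbed-end-capped seeds under a pointed-end
capper titration, and dilution-induced depolymerization.

All concentrations are in µM, times in s.  Measurement noise is
additive Gaussian on the reported signal only; ground truth is stored
noiseless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "AVOGADRO",
    "MOLECULES_PER_UM_FL",
    "RateConstants",
    "NucleationParams",
    "CapperParams",
    "BulkCondition",
    "FluorescenceTrace",
    "AssemblyResult",
    "GillespieResult",
    "BARBED_END",
    "POINTED_END",
    "capper_occupancy",
    "simulate_spontaneous_assembly",
    "gillespie_assembly",
    "simulate_pointed_elongation",
    "simulate_dilution_depolymerization",
]

AVOGADRO = 6.02214076e23
#: molecules per (µM · fL): 1e-6 mol/L * 1e-15 L * N_A
MOLECULES_PER_UM_FL = 1e-6 * 1e-15 * AVOGADRO


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class RateConstants:
    """Association/dissociation rate constants at one filament end.

    Attributes
    ----------
    k_on : float
        Association rate constant, µM⁻¹ s⁻¹.
    k_off : float
        Dissociation rate constant, s⁻¹.
    """

    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        _require_finite(k_on=self.k_on, k_off=self.k_off)
        if self.k_on <= 0:
            raise ValueError("k_on must be > 0")
        if self.k_off < 0:
            raise ValueError("k_off must be >= 0")

    @property
    def cc(self) -> float:
        """Critical concentration k_off / k_on, µM."""
        return self.k_off / self.k_on


#: Barbed-end rate constants for Mg-ATP-actin (cc ≈ 0.136 µM).
BARBED_END = RateConstants(k_on=10.3, k_off=1.4)

#: Pointed-end rate constants (textbook values, cc ≈ 0.6 µM).
POINTED_END = RateConstants(k_on=1.3, k_off=0.8)


@dataclass(frozen=True)
class NucleationParams:
    """Spontaneous-nucleation rate law dN/dt = k_nuc_eff · G^n_c.

    ``k_nuc_eff = k_nuc_base · (1 + enhancement_per_capper · [capper])``
    is a phenomenological linear enhancement: pointed-end cappers of the
    thioredoxin-fold family stimulate nucleation, presumably by
    stabilizing dimers/trimers, but no mechanistic rate law is
    established, so a multiplier on the base coefficient is used.
    """

    k_nuc_base: float = 2e-6  # µM^(1-n_c) s⁻¹
    n_c: int = 3  # trimeric nucleus
    enhancement_per_capper: float = 0.0  # µM⁻¹

    def __post_init__(self) -> None:
        _require_finite(
            k_nuc_base=self.k_nuc_base,
            enhancement_per_capper=self.enhancement_per_capper,
        )
        if self.n_c < 2:
            raise ValueError("n_c must be >= 2")
        if self.k_nuc_base < 0:
            raise ValueError("k_nuc_base must be >= 0")
        if self.enhancement_per_capper < 0:
            raise ValueError("enhancement_per_capper must be >= 0")

    def k_nuc_eff(self, capper_conc: float) -> float:
        return self.k_nuc_base * (1.0 + self.enhancement_per_capper * capper_conc)


@dataclass(frozen=True)
class CapperParams:
    """Rapid-equilibrium pointed-end capper.

    Occupancy θ = c/(kd_pe + c) is instantaneous in the capper
    concentration c.  At saturation the capper blocks a fraction
    ``block_fraction`` of elongation and a fraction ``protect_fraction``
    of depolymerization; both may be < 1 (partial cap).
    """

    name: str
    kd_pe: float  # µM
    protect_fraction: float = 1.0
    block_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.kd_pe <= 0:
            raise ValueError("kd_pe must be > 0")
        for attr in ("protect_fraction", "block_fraction"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must lie in [0, 1]")

    def occupancy(self, conc: float) -> float:
        return capper_occupancy(conc, self.kd_pe)


def capper_occupancy(conc: float, kd: float) -> float:
    """Fractional pointed-end occupancy θ = c/(K_D + c)."""
    if conc < 0:
        raise ValueError("capper concentration must be >= 0")
    if kd <= 0:
        raise ValueError("kd must be > 0")
    return conc / (kd + conc)


@dataclass(frozen=True)
class BulkCondition:
    """One well of a bulk pyrene polymerization assay."""

    a_total: float  # total actin, µM
    seed_ends: float = 0.0  # initial filament ends, µM
    capper_conc: float = 0.0  # µM
    g0: Optional[float] = None  # initial free monomer; defaults to a_total

    def __post_init__(self) -> None:
        if self.g0 is None:
            object.__setattr__(self, "g0", self.a_total)
        if not 0.0 <= self.g0 <= self.a_total:
            raise ValueError("need 0 <= g0 <= a_total")
        if self.seed_ends < 0:
            raise ValueError("seed_ends must be >= 0")
        if self.capper_conc < 0:
            raise ValueError("capper_conc must be >= 0")


@dataclass
class FluorescenceTrace:
    """Time-stamped kinetic signal from a plate-reader well.

    ``f`` is in arbitrary units unless ``normalized`` is set, in which
    case it is the polymer mass fraction F_norm ∈ [0, 1] (up to noise).
    """

    t: np.ndarray
    f: np.ndarray
    normalized: bool = False
    condition: object = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.f.shape:
            raise ValueError("t and f must be 1-D arrays of equal length")
        if len(self.t) < 3:
            raise ValueError("a trace needs at least 3 points")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("time points must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class AssemblyResult:
    """ODE simulation output: observed trace plus noiseless ground truth."""

    trace: FluorescenceTrace
    ends: np.ndarray  # noiseless filament-end concentration N(t), µM
    polymer: np.ndarray  # noiseless P(t), µM
    monomer: np.ndarray  # noiseless G(t), µM


def simulate_spontaneous_assembly(
    cond: BulkCondition,
    rates: RateConstants = BARBED_END,
    nuc: NucleationParams = NucleationParams(),
    t_end: float = 2000.0,
    n_points: int = 400,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> AssemblyResult:
    """Deterministic nucleation–elongation simulation of a bulk assay.

    Integrates, with G = a_total − P::

        dN/dt = k_nuc_eff · G^n_c
        dP/dt = N · (k_on·G − k_off) + n_c · k_nuc_eff · G^n_c

    (each new nucleus contributes n_c subunits to polymer) and reports
    the normalized pyrene signal F_norm(t) = P/(a_total − cc) clipped to
    [0, 1], with additive Gaussian noise of SD ``noise_sd``.
    """
    if cond.g0 <= 0:
        raise ValueError("g0 must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    _require_finite(t_end=t_end, noise_sd=noise_sd)

    k_on, k_off = rates.k_on, rates.k_off
    k_nuc = nuc.k_nuc_eff(cond.capper_conc)
    n_c = nuc.n_c
    a_total = cond.a_total

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        n, p = y
        g = max(a_total - p, 0.0)
        r_nuc = k_nuc * g**n_c
        return [r_nuc, n * (k_on * g - k_off) + n_c * r_nuc]

    t_eval = np.linspace(0.0, t_end, n_points)
    y0 = [cond.seed_ends, a_total - cond.g0]
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, t_eval=t_eval, method="LSODA",
        rtol=1e-8, atol=1e-12,
    )
    if not sol.success:  # pragma: no cover - LSODA is robust here
        raise RuntimeError(f"ODE integration failed: {sol.message}")

    ends = sol.y[0]
    polymer = sol.y[1]
    monomer = a_total - polymer
    denom = a_total - rates.cc
    if denom <= 0:
        # below the critical concentration nothing assembles; report zeros
        f_norm = np.zeros_like(polymer)
    else:
        f_norm = np.clip(polymer / denom, 0.0, 1.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f_norm = f_norm + rng.normal(0.0, noise_sd, size=f_norm.shape)
    trace = FluorescenceTrace(t_eval, f_norm, normalized=True, condition=cond)
    return AssemblyResult(trace=trace, ends=ends, polymer=polymer, monomer=monomer)


@dataclass
class GillespieResult:
    """State of one SSA run sampled on a fixed time grid (counts)."""

    t: np.ndarray
    monomer: np.ndarray
    polymer: np.ndarray
    ends: np.ndarray
    volume_fl: float

    @property
    def omega(self) -> float:
        """Molecules per µM for this volume."""
        return self.volume_fl * MOLECULES_PER_UM_FL

    def concentrations(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(monomer, polymer, ends) in µM."""
        w = self.omega
        return self.monomer / w, self.polymer / w, self.ends / w


def gillespie_assembly(
    cond: BulkCondition,
    rates: RateConstants = BARBED_END,
    nuc: NucleationParams = NucleationParams(),
    volume_fl: float = 1.0,
    t_end: float = 2000.0,
    n_points: int = 400,
    seed: Optional[int] = None,
    max_events: int = 20_000_000,
) -> GillespieResult:
    """Exact SSA over {nucleation, elongation, shrinkage}.

    Reactions: n_c monomers → one filament of n_c subunits (propensity
    k_nuc_eff·(g/Ω)^n_c·Ω, the macroscopic-rate form); +1 subunit per
    end (k_on·(g/Ω)·ends); −1 subunit per end (k_off·ends).  Mass
    (monomer + polymerized subunits) is conserved at every event.
    """
    omega = volume_fl * MOLECULES_PER_UM_FL
    g = int(round(cond.g0 * omega))
    p = int(round((cond.a_total - cond.g0) * omega))
    m = int(round(cond.seed_ends * omega))
    total = g + p
    if total > 1_000_000:
        raise ValueError(
            f"{total} molecules exceeds the 1e6 SSA limit; reduce volume_fl"
        )
    k_on, k_off = rates.k_on, rates.k_off
    k_nuc = nuc.k_nuc_eff(cond.capper_conc)
    n_c = nuc.n_c

    rng = np.random.default_rng(seed)
    t_grid = np.linspace(0.0, t_end, n_points)
    out_g = np.empty(n_points, dtype=np.int64)
    out_p = np.empty(n_points, dtype=np.int64)
    out_m = np.empty(n_points, dtype=np.int64)

    t = 0.0
    idx = 0
    events = 0
    while True:
        a_nuc = k_nuc * (g / omega) ** n_c * omega if g >= n_c else 0.0
        a_el = k_on * (g / omega) * m if g > 0 else 0.0
        a_sh = k_off * m if p > 0 else 0.0
        a_tot = a_nuc + a_el + a_sh
        if a_tot <= 0.0:
            t_next = np.inf
        else:
            t_next = t + rng.exponential(1.0 / a_tot)
        while idx < n_points and t_grid[idx] <= min(t_next, t_end):
            out_g[idx], out_p[idx], out_m[idx] = g, p, m
            idx += 1
        if t_next > t_end or idx >= n_points:
            break
        t = t_next
        u = rng.random() * a_tot
        if u < a_nuc:
            g -= n_c
            m += 1
            p += n_c
        elif u < a_nuc + a_el:
            g -= 1
            p += 1
        else:
            g += 1
            p -= 1
        events += 1
        if events > max_events:
            raise RuntimeError(
                f"SSA exceeded {max_events} events; the system/volume is too "
                "large for an exact simulation"
            )
        assert g + p == total, "mass conservation violated"
    # fill any trailing grid points with the final state
    while idx < n_points:
        out_g[idx], out_p[idx], out_m[idx] = g, p, m
        idx += 1
    return GillespieResult(
        t=t_grid, monomer=out_g, polymer=out_p, ends=out_m, volume_fl=volume_fl
    )


def simulate_pointed_elongation(
    seed_ends: float,
    g0: float,
    capper: Optional[CapperParams] = None,
    capper_conc: float = 0.0,
    rates_pe: RateConstants = POINTED_END,
    t_end: float = 600.0,
    n_points: int = 300,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    f_scale: float = 1.0,
) -> FluorescenceTrace:
    """Seeded pointed-end elongation trace (barbed ends CP-blocked).

    With rapid-equilibrium occupancy θ at the pointed end, the active
    end concentration is E = seed_ends·(1 − block_fraction·θ) and::

        dP/dt = E · (k_on_pe·G − k_off_pe),   G = g0 − P

    which integrates to P(t) = (g0 − cc_pe)·(1 − exp(−E·k_on_pe·t)),
    clipped at 0 when g0 is below the pointed-end critical
    concentration.  The returned raw-scale signal is f_scale·P plus
    Gaussian noise.
    """
    if seed_ends <= 0:
        raise ValueError("seed_ends must be > 0")
    if g0 < 0 or capper_conc < 0:
        raise ValueError("concentrations must be >= 0")
    theta = capper.occupancy(capper_conc) if capper is not None else 0.0
    block = capper.block_fraction if capper is not None else 0.0
    e_active = seed_ends * (1.0 - block * theta)
    t = np.linspace(0.0, t_end, n_points)
    p_inf = g0 - rates_pe.cc
    p = p_inf * (1.0 - np.exp(-e_active * rates_pe.k_on * t))
    p = np.maximum(p, 0.0)
    f = f_scale * p
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    return FluorescenceTrace(t, f, normalized=False, condition=capper)


def simulate_dilution_depolymerization(
    f0: float = 1.0,
    k_dep0: float = 0.01,
    capper: Optional[CapperParams] = None,
    capper_conc: float = 0.0,
    f_inf: float = 0.0,
    t_end: float = 600.0,
    n_points: int = 300,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> FluorescenceTrace:
    """Dilution-induced pointed-end depolymerization decay.

    F(t) = F_∞ + (f0 − F_∞)·exp(−k_app·t) with the apparent rate
    constant reduced by capper protection:
    k_app = k_dep0·(1 − protect_fraction·θ).
    """
    if k_dep0 <= 0:
        raise ValueError("k_dep0 must be > 0")
    if capper_conc < 0:
        raise ValueError("capper_conc must be >= 0")
    theta = capper.occupancy(capper_conc) if capper is not None else 0.0
    protect = capper.protect_fraction if capper is not None else 0.0
    k_app = k_dep0 * (1.0 - protect * theta)
    t = np.linspace(0.0, t_end, n_points)
    f = f_inf + (f0 - f_inf) * np.exp(-k_app * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    return FluorescenceTrace(t, f, normalized=False, condition=capper)
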