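"""Sequence-based hydrodynamic arithmetic for sedimentation velocity.

Supports the interpretation of analytical ultracentrifugation runs:

* molar mass from amino-acid composition (average isotope masses),
* partial specific volume v̄ by the Cohn–Edsall mass-weighted average
  of tabulated residue values,
* correction of an experimental sedimentation coefficient to standard
  conditions (water, 20 °C):

      s20,w = s_exp · (η_b/η_20,w) · (1 − v̄·ρ_20,w)/(1 − v̄·ρ_b)

* the frictional ratio f/f0 relative to the equivalent anhydrous
  sphere:  f = M(1 − v̄ρ)/(N_A·s),  f0 = 6πη·R0 with
  R0 = (3Mv̄/(4πN_A))^(1/3).

Svedberg units throughout (1 S = 1e-13 s); internal friction
arithmetic is in CGS units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.SeqUtils import molecular_weight

__all__ = [
    "RHO_WATER_20C",
    "ETA_WATER_20C_CP",
    "VBAR_RESIDUE_ML_G",
    "HydroRecord",
    "mass_from_sequence",
    "vbar_cohn_edsall",
    "s20w_correction",
    "frictional_ratio",
    "sphere_sedimentation_coefficient",
    "hydro_record",
    "analyze_fasta",
]

AVOGADRO = 6.02214076e23
WATER_MASS = 18.01528  # g/mol, average

#: density of water at 20 °C, g/mL
RHO_WATER_20C = 0.99823
#: viscosity of water at 20 °C, cP
ETA_WATER_20C_CP = 1.002

#: Cohn–Edsall partial specific volumes of amino-acid residues, mL/g.
#: Standard consensus values as tabulated in the sedimentation
#: literature (see docs/methods.md for provenance).
VBAR_RESIDUE_ML_G = {
    "A": 0.74, "R": 0.70, "N": 0.62, "D": 0.60, "C": 0.63,
    "Q": 0.67, "E": 0.66, "G": 0.64, "H": 0.67, "I": 0.90,
    "L": 0.90, "K": 0.82, "M": 0.75, "F": 0.77, "P": 0.76,
    "S": 0.63, "T": 0.70, "W": 0.74, "Y": 0.71, "V": 0.86,
}

# average residue masses (free amino acid minus one water), g/mol
_AA_MASS = {
    aa: molecular_weight(aa, seq_type="protein") for aa in VBAR_RESIDUE_ML_G
}
_RESIDUE_MASS = {aa: m - WATER_MASS for aa, m in _AA_MASS.items()}


@dataclass
class HydroRecord:
    """Hydrodynamic summary of one protein."""

    name: str
    sequence: str
    molar_mass: float  # g/mol
    vbar: float  # mL/g
    s20w: Optional[float] = None  # Svedberg
    f_over_f0: Optional[float] = None


def _validate_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = [(i, c) for i, c in enumerate(seq) if c not in VBAR_RESIDUE_ML_G]
    if bad:
        shown = ", ".join(f"{c!r} at {i}" for i, c in bad[:5])
        raise ValueError(f"non-canonical residues: {shown}")
    return seq


def mass_from_sequence(sequence: str) -> float:
    """Average-isotope molar mass of a protein, g/mol.

    Residue masses summed plus one water for the free termini.
    """
    seq = _validate_sequence(sequence)
    return sum(_RESIDUE_MASS[c] for c in seq) + WATER_MASS


def vbar_cohn_edsall(sequence: str) -> float:
    """Partial specific volume by the Cohn–Edsall method, mL/g.

    Mass-weighted average of tabulated residue v̄ values over the
    residue mass fractions of the sequence.
    """
    seq = _validate_sequence(sequence)
    total_mass = 0.0
    weighted = 0.0
    for c in seq:
        m = _RESIDUE_MASS[c]
        total_mass += m
        weighted += m * VBAR_RESIDUE_ML_G[c]
    vbar = weighted / total_mass
    if not 0.6 < vbar < 0.8:
        warnings.warn(
            f"v̄ = {vbar:.3f} mL/g is outside the typical protein range "
            "(0.6–0.8)", stacklevel=2,
        )
    return vbar


def s20w_correction(
    s_exp: float, rho_buffer: float, eta_buffer: float, vbar: float
) -> float:
    """Correct an experimental s-value (S) to water at 20 °C.

    ``rho_buffer`` in g/mL, ``eta_buffer`` in cP.
    """
    for name, rho in (("buffer", rho_buffer), ("water", RHO_WATER_20C)):
        if 1.0 - vbar * rho <= 0:
            raise ValueError(
                f"buoyancy term 1 − v̄·ρ_{name} is non-positive; "
                "check v̄ and density"
            )
    return (
        s_exp
        * (eta_buffer / ETA_WATER_20C_CP)
        * (1.0 - vbar * RHO_WATER_20C)
        / (1.0 - vbar * rho_buffer)
    )


def _sphere_friction(molar_mass: float, vbar: float) -> float:
    """f0 = 6πη·R0 of the equivalent anhydrous sphere, CGS (g/s)."""
    r0_cm = (3.0 * molar_mass * vbar / (4.0 * 3.141592653589793 * AVOGADRO)) ** (
        1.0 / 3.0
    )
    eta_poise = ETA_WATER_20C_CP * 1e-2
    return 6.0 * 3.141592653589793 * eta_poise * r0_cm


def frictional_ratio(s20w: float, molar_mass: float, vbar: float) -> float:
    """Frictional ratio f/f0 from s20,w (S), molar mass and v̄.

    Values below 1 (hydrodynamically impossible) trigger a warning but
    are returned so inconsistent inputs remain visible.
    """
    if min(s20w, molar_mass, vbar) <= 0:
        raise ValueError("s20w, molar_mass and vbar must be > 0")
    buoyancy = 1.0 - vbar * RHO_WATER_20C
    if buoyancy <= 0:
        raise ValueError("1 − v̄·ρ_20,w must be > 0")
    f = molar_mass * buoyancy / (AVOGADRO * s20w * 1e-13)
    ratio = f / _sphere_friction(molar_mass, vbar)
    if ratio < 1.0 - 1e-6:
        warnings.warn(
            f"f/f0 = {ratio:.3f} < 1: inputs are mutually inconsistent",
            stacklevel=2,
        )
    return ratio


def sphere_sedimentation_coefficient(molar_mass: float, vbar: float) -> float:
    """s (in S) of the equivalent anhydrous sphere in water at 20 °C."""
    buoyancy = 1.0 - vbar * RHO_WATER_20C
    s_sec = molar_mass * buoyancy / (AVOGADRO * _sphere_friction(molar_mass, vbar))
    return s_sec / 1e-13


def hydro_record(
    name: str,
    sequence: str,
    s_exp: Optional[float] = None,
    rho_buffer: float = RHO_WATER_20C,
    eta_buffer: float = ETA_WATER_20C_CP,
) -> HydroRecord:
    """Full composition-based hydrodynamic summary of one sequence."""
    mass = mass_from_sequence(sequence)
    vbar = vbar_cohn_edsall(sequence)
    s20w = f_ratio = None
    if s_exp is not None:
        s20w = s20w_correction(s_exp, rho_buffer, eta_buffer, vbar)
        f_ratio = frictional_ratio(s20w, mass, vbar)
    return HydroRecord(
        name=name, sequence=_validate_sequence(sequence),
        molar_mass=mass, vbar=vbar, s20w=s20w, f_over_f0=f_ratio,
    )


def analyze_fasta(
    path: str | Path,
    s_values: Optional[dict[str, float]] = None,
    rho_buffer: float = RHO_WATER_20C,
    eta_buffer: float = ETA_WATER_20C_CP,
) -> list[HydroRecord]:
    """Hydrodynamic summaries for every record of a FASTA file.

    ``s_values`` optionally maps record ids to experimental s-values
    (S) to be corrected and turned into frictional ratios.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s_exp = (s_values or {}).get(rec.id)
        records.append(
            hydro_record(rec.id, str(rec.seq), s_exp=s_exp,
                         rho_buffer=rho_buffer, eta_buffer=eta_buffer)
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records
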