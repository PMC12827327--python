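"""Published reference values used as simulator defaults and oracles.

These are literature measurements for skeletal α-actin and the
pointed-end cappers tropomodulin-3 and the thioredoxin-fold capper
family (TPEC / SH3BGRL isoforms).  They parameterize the synthetic-data
generators so that recovery tests run under realistic conditions, and
serve as the ground truth those tests try to recover.
"""

from __future__ import annotations

__all__ = [
    "K_ON_BARBED",
    "K_OFF_BARBED",
    "POINTED_END_CC",
    "ELONGATION_KD_UM",
    "DEPOL_K_HALF_UM",
    "TIRF_ELONGATION_NM_S",
    "TIRF_NUCLEATION_RATE",
    "AUC_S20W",
    "AUC_MOLAR_MASS_KG_MOL",
    "AUC_FRICTIONAL_RATIO",
]

#: barbed-end association rate constant, µM⁻¹ s⁻¹ (TIRF-derived)
K_ON_BARBED = 10.3
#: barbed-end dissociation rate constant, s⁻¹
K_OFF_BARBED = 1.4
#: approximate pointed-end critical concentration, µM
POINTED_END_CC = 0.6

#: apparent K_D for inhibition of pointed-end elongation, µM
ELONGATION_KD_UM = {
    "tmod3": 0.180,
    "sh3bgrl": 0.085,
    "sh3bgrl3": 0.031,
}

#: half-maximal protection against pointed-end depolymerization, µM
#: (K_D for tropomodulin-3; K_50% for the TPEC isoforms, whose maximal
#: protection is partial)
DEPOL_K_HALF_UM = {
    "tmod3": 0.13,
    "sh3bgrl": 7.6,
    "sh3bgrl3": 7.7,
}

#: apparent filament elongation rate (actin only), mean ± SD, nm/s
TIRF_ELONGATION_NM_S = (28.1, 4.5)

#: apparent filament nucleation rate k_nuc, µm⁻² s⁻¹ (1 µM α-actin)
TIRF_NUCLEATION_RATE = {
    "actin_only": 5.1e-6,
    "sh3bgrl_1uM": 12.3e-6,
    "sh3bgrl_5uM": 22.2e-6,
    "sh3bgrl2_1uM": 7.0e-6,
    "sh3bgrl2_5uM": 12.0e-6,
    "sh3bgrl3_0p5uM": 10.5e-6,
    "sh3bgrl3_1uM": 13.8e-6,
    "sh3bgrl3_2uM": 18.4e-6,
    "sh3bgrl3_5uM": 34.2e-6,
}

#: sedimentation coefficients s20,w of the TPEC isoforms, S
AUC_S20W = {"sh3bgrl": 1.55, "sh3bgrl2": 1.49, "sh3bgrl3": 1.41}

#: experimentally determined molar masses, kg/mol
AUC_MOLAR_MASS_KG_MOL = {"sh3bgrl": 13.0, "sh3bgrl2": 12.4, "sh3bgrl3": 10.1}

#: frictional ratios f/f0
AUC_FRICTIONAL_RATIO = {"sh3bgrl": 1.32, "sh3bgrl2": 1.30, "sh3bgrl3": 1.27}
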