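"""Sequence-based sedimentation-velocity arithmetic.

From an amino-acid sequence: average-isotope molar mass and
Cohn–Edsall partial specific volume; from an experimental s-value:
the s20,w correction and the frictional ratio f/f0 (shape deviation
from the equivalent anhydrous sphere).  A ~13 kg/mol thioredoxin-fold
monomer sedimenting at 1.55 S has f/f0 ≈ 1.3 — moderately elongated.
"""

from actokin import frictional_ratio, hydro_record, s20w_correction

# synthetic demonstration sequence (not a natural protein)
SEQ = "MSKVLEAYDFLTKHPEVKGQWVCLFGSEEAIKAVEGNPRLVFLKDGQ" * 3

rec = hydro_record("demo_monomer", SEQ)
print(f"molar mass            : {rec.molar_mass/1000:.2f} kg/mol")
print(f"partial spec. volume  : {rec.vbar:.3f} mL/g (Cohn-Edsall)")

s_exp = 1.42  # S, measured in a buffer denser/more viscous than water
s20w = s20w_correction(s_exp, rho_buffer=1.004, eta_buffer=1.05, vbar=rec.vbar)
ratio = frictional_ratio(s20w, rec.molar_mass, rec.vbar)
print(f"s_exp = {s_exp:.2f} S  ->  s20,w = {s20w:.2f} S")
print(f"frictional ratio f/f0 : {ratio:.2f}")
# f/f0 = 1 is a perfect sphere; globular monomers typically 1.2-1.4.
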