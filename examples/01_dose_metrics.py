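"""Convert particle exposure concentrations between dose metrics.

A 5 µg/mL ZnO suspension is expressed as constituent-metal mass, molar
metal concentration, and particle surface area per volume.
"""

from toxpod import mean_ssa, metal_mass_conc, metal_molar_conc, ssa_conc

conc = 5.0  # µg/mL ZnO
print(f"ZnO at {conc:.2f} ug/mL:")
print(f"  metal mass : {metal_mass_conc(conc, 'ZnO'):7.2f} ug/mL Zn")
print(f"  metal molar: {metal_molar_conc(conc, 'ZnO'):7.2f} uM Zn")
print(f"  surface    : {ssa_conc(conc, 35.0):7.2f} cm2/mL (SSA 35 m2/g)")
print(f"  bulk-particle SSA from a 2-15.8 m2/g range: {mean_ssa((2.0, 15.8))} m2/g")
# The three dose metrics let potency be compared on mass-of-metal or
# particle-surface scales instead of compound mass alone.
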