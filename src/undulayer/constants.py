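"""Physical constants and unit conversions.

Internal units are nm (length), ns (time) and amu (mass); SI appears only in
the elasticity chain and in densities (kg/m^3).
"""

#: Boltzmann constant, J/K (CODATA 2018, exact).
K_B = 1.380649e-23

#: Atomic mass unit, kg (CODATA 2018).
AMU_KG = 1.66053906892e-27

#: nm^3 in m^3.
NM3_M3 = 1e-27

#: Convert a mass in amu per volume in nm^3 to kg/m^3.
AMU_PER_NM3_TO_KG_M3 = AMU_KG / NM3_M3  # ~1.6605

#: Molar mass of water, amu (TIP3P-like single bead).
WATER_MASS = 18.0153

#: Total mass of one escin (aescin) molecule, amu.
ESCIN_MASS = 1101.0

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 293.0
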