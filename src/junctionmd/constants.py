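"""Physical constants and unit helpers.

Energies are kcal/mol unless noted; lengths in Å, angles in degrees,
temperatures in K.
"""

# Boltzmann / gas constant per mole
KB_KCAL = 1.987204e-3  # kcal mol^-1 K^-1
R_KJ = 8.31446e-3      # kJ mol^-1 K^-1
KCAL_TO_KJ = 4.184

# SI values used by the Schlitter entropy (per-molecule bookkeeping)
KB_SI = 1.380649e-23       # J/K
HBAR_SI = 1.054571817e-34  # J s
AMU_SI = 1.66053906660e-27  # kg
ANGSTROM_SI = 1.0e-10      # m
AVOGADRO = 6.02214076e23
J_PER_KCAL = 4184.0

DEFAULT_TEMPERATURE = 298.0  # K, the simulation temperature


def kT_kcal(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB_KCAL * temperature
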