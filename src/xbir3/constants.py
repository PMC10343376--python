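"""Physical constants in the molar/Å/kcal unit system used throughout.

Energies are kcal/mol, distances Å, charges in elementary charges,
masses in amu, temperatures in K.
"""

#: Coulomb conversion factor, kcal·Å/(mol·e²) (CHARMM convention).
COULOMB_CONSTANT = 332.0636

#: Molar gas constant, kcal·K⁻¹·mol⁻¹.
GAS_CONSTANT = 1.9858775e-3

#: Default analysis temperature, K.
DEFAULT_TEMPERATURE = 303.15

#: Avogadro's number, mol⁻¹.
AVOGADRO = 6.02214076e23

#: Speed of light, cm/s (for wavenumber conversion).
SPEED_OF_LIGHT_CM = 2.99792458e10

#: Planck constant over Boltzmann constant, K·s (h/kB, for QHO entropy).
H_OVER_KB = 4.799243073e-11

#: Water probe radius for SASA, Å.
PROBE_RADIUS = 1.4

#: SASA-linear non-polar solvation model: G = slope·SASA + intercept.
NONPOLAR_SLOPE = 0.00542   # kcal/mol/Å²
NONPOLAR_INTERCEPT = 0.92  # kcal/mol


def rt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """k_B·T per mole (= R·T), kcal/mol."""
    return GAS_CONSTANT * temperature
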