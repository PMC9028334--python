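"""Physical constants and unit conventions.

The package works in a single unit system throughout: lengths in
Angstrom (Å), times in nanoseconds (ns), energies in kcal/mol,
temperatures in Kelvin, charges in elementary charges (e), dipole
moments in Debye, permeabilities in cm³·s⁻¹.
"""

#: Boltzmann constant / gas constant in kcal·mol⁻¹·K⁻¹.
KB_KCAL_MOL_K = 1.9872041e-3

#: Gas constant, identical to ``KB_KCAL_MOL_K`` in molar units.
R_KCAL_MOL_K = KB_KCAL_MOL_K

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 310.15

#: Volume of a single water molecule (cm³): 18.07 cm³/mol / N_A.
V_WATER_CM3 = 2.989e-23

#: 1 e·Å expressed in Debye.
EA_TO_DEBYE = 4.80320425

#: Elementary charge (C).
E_CHARGE = 1.602176634e-19

#: Vacuum permittivity (F/m).
EPS0 = 8.8541878128e-12

#: ns⁻¹ → s⁻¹.
PER_NS_TO_PER_S = 1.0e9


def kt(temperature: float) -> float:
    """Thermal energy k_B·T in kcal/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_MOL_K * temperature
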