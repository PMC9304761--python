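"""Physical constants and default thermodynamic conventions.

Units used throughout the package: kcal/mol for energies, Angstrom (A) for
lengths, picoseconds for times, Kelvin for temperatures.
"""

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_MOL_K = 1.9872041e-3

#: Default simulation temperature (21.85 degrees C).
T_SIM_K = 295.0

#: Standard-state volume per molecule at 1 M, in A^3.
V0_A3 = 1663.0

#: Hard cap on the repulsive inner core of the toy potential, kcal/mol.
#: Keeps configurational integrals finite without affecting any region the
#: dynamics actually visits at the temperatures of interest.
CORE_CAP_KCAL_MOL = 50.0


def kbt(temperature: float) -> float:
    """Thermal energy kB*T in kcal/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_MOL_K * temperature
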