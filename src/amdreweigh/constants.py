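"""Physical constants and unit conventions.

Energies are kcal/mol, distances Angstrom, angles degrees, temperatures
Kelvin throughout the package.
"""

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL = 0.0019872041

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 300.0


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL * temperature
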