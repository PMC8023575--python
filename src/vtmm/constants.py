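"""Physical constants and unit conventions.

The package works throughout in angstrom (length), picosecond (time),
kcal/mol (energy) and kelvin (temperature).
"""

#: Boltzmann constant, kcal/(mol K).
KB_KCAL_MOL_K = 0.0019872

#: Default thermostat temperature, K.
DEFAULT_TEMPERATURE = 310.0


def kT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB_KCAL_MOL_K * temperature
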