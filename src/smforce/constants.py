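"""Physical constants in the pN/nm/K unit system used throughout the package."""

#: Boltzmann constant in pN·nm/K (1.380649e-23 J/K).
KB_PN_NM = 1.380649e-2

ROOM_TEMPERATURE_K = 298.0


def thermal_energy(temperature: float = ROOM_TEMPERATURE_K) -> float:
    """kB·T in pN·nm (≈ 4.11 pN·nm at 298 K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_PN_NM * temperature
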