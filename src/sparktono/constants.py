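"""Physical constants and unit conversions used throughout the package."""

#: Pascals per millimetre of mercury.
MMHG_TO_PA: float = 133.322

#: Universal gas constant, J / (mol K).
R_GAS: float = 8.314

#: Specific gas constant of dry air, J / (kg K).
AIR_SPECIFIC_GAS_CONSTANT: float = 287.05

#: Heat-capacity ratio of air (diatomic, room temperature).
AIR_GAMMA: float = 1.4

#: Room temperature used for air-property defaults, K (20 degC).
ROOM_TEMPERATURE_K: float = 293.15

#: Standard atmospheric pressure, Pa.
ATM_PA: float = 101_325.0

#: O=O bond dissociation energy, J/mol.
O2_BOND_ENERGY_J_PER_MOL: float = 498_000.0


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_TO_PA


def sound_speed_air(temperature_K: float = ROOM_TEMPERATURE_K,
                    gamma: float = AIR_GAMMA,
                    specific_gas_const: float = AIR_SPECIFIC_GAS_CONSTANT) -> float:
    """Speed of sound in air, c = sqrt(gamma * R_s * T), m/s."""
    return (gamma * specific_gas_const * temperature_K) ** 0.5
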