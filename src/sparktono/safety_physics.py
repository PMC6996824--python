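"""Closed-form safety physics of the spark-gap shock-wave source.

All quantities a clinical safety assessment of the spark source can compute
on paper: stored capacitor energy, a worst-case ozone budget (assuming every
joule dissociates O2), the ideal-gas air inventory of an unventilated room,
the normal-shock peak overpressure at a given Mach number, and the Mach
number of the shock front from high-speed camera frames.

Note on the pressure jump: the peak overpressure is computed from the
Rankine-Hugoniot normal-shock relation
``p2/p1 = 1 + (2 gamma / (gamma + 1)) (M^2 - 1)``,
which gives 1.51 bar at M = 1.2 with 1 bar ambient.  An isentropic
stagnation estimate at the same Mach number would give ~2.4 bar; the
normal-shock static jump is the appropriate figure for the pressure felt
behind a passing shock front.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import (AIR_GAMMA, AIR_SPECIFIC_GAS_CONSTANT, ATM_PA,
                        O2_BOND_ENERGY_J_PER_MOL, R_GAS, ROOM_TEMPERATURE_K,
                        sound_speed_air)
from .errors import ParameterError

__all__ = [
    "SparkSpec",
    "RoomSpec",
    "ShockSpec",
    "OzoneReport",
    "MachResult",
    "capacitor_energy",
    "moles_of_air",
    "ozone_budget",
    "shock_peak_pressure",
    "mach_from_frames",
    "air_path_delay_change",
    "full_report",
]


@dataclass(frozen=True)
class SparkSpec:
    """Spark-gap drive: capacitor bank and charging voltage."""

    capacitance_F: float = 167e-9
    voltage_V: float = 10e3

    def __post_init__(self) -> None:
        if self.capacitance_F <= 0 or self.voltage_V <= 0:
            raise ParameterError("capacitance and voltage must be > 0")


@dataclass(frozen=True)
class RoomSpec:
    """An unventilated room treated as an ideal-gas reservoir."""

    volume_m3: float = 48.0  # 4 m x 4 m x 3 m
    temperature_K: float = ROOM_TEMPERATURE_K
    pressure_Pa: float = ATM_PA

    def __post_init__(self) -> None:
        if min(self.volume_m3, self.temperature_K, self.pressure_Pa) <= 0:
            raise ParameterError("room volume, temperature and pressure must be > 0")


@dataclass(frozen=True)
class ShockSpec:
    """A normal shock of given Mach number in ambient air."""

    mach: float = 1.2
    gamma: float = AIR_GAMMA
    ambient_pressure_Pa: float = 1e5  # 1 bar

    def __post_init__(self) -> None:
        if self.mach < 1:
            raise ParameterError(f"shock requires mach >= 1, got {self.mach}")
        if self.gamma <= 1:
            raise ParameterError(f"gamma must be > 1, got {self.gamma}")
        if self.ambient_pressure_Pa <= 0:
            raise ParameterError("ambient pressure must be > 0")


@dataclass(frozen=True)
class OzoneReport:
    """Worst-case per-spark ozone budget in a sealed room."""

    energy_J: float
    moles_O2_dissociated: float
    moles_O3: float
    moles_air: float
    concentration_ppb: float


@dataclass(frozen=True)
class MachResult:
    """Shock-front kinematics estimated from camera frames."""

    front_speed_m_s: float
    sound_speed_m_s: float
    mach: float

    @property
    def supersonic(self) -> bool:
        return self.mach >= 1.0


def capacitor_energy(spark: SparkSpec) -> float:
    """Stored energy E = C V^2 / 2, joules."""
    return 0.5 * spark.capacitance_F * spark.voltage_V ** 2


def moles_of_air(room: RoomSpec) -> float:
    """Ideal-gas mole count n = P V / (R T)."""
    return room.pressure_Pa * room.volume_m3 / (R_GAS * room.temperature_K)


def ozone_budget(energy_J: float, room: RoomSpec | None = None,
                 bond_energy_J_per_mol: float = O2_BOND_ENERGY_J_PER_MOL,
                 ) -> OzoneReport:
    """Worst-case ozone from one spark, assuming all energy splits O2.

    The corona chemistry is ``O2 -> 2 O`` followed by ``O2 + O -> O3``, so
    each dissociated O2 yields two O3 molecules.  The concentration is the
    molar fraction of O3 in the room's air, in parts per billion.
    """
    if energy_J < 0:
        raise ParameterError("energy_J must be >= 0")
    room = room or RoomSpec()
    n_o2 = energy_J / bond_energy_J_per_mol
    n_o3 = 2.0 * n_o2
    n_air = moles_of_air(room)
    return OzoneReport(energy_J=energy_J, moles_O2_dissociated=n_o2,
                       moles_O3=n_o3, moles_air=n_air,
                       concentration_ppb=1e9 * n_o3 / n_air)


def shock_peak_pressure(shock: ShockSpec) -> tuple[float, float]:
    """Post-shock static pressure behind a normal shock.

    Returns ``(pascals, bar)`` from the Rankine-Hugoniot jump
    ``p2/p1 = 1 + (2 gamma / (gamma + 1)) (M^2 - 1)``; the ratio is 1 at
    M = 1 and strictly increasing in M.
    """
    g, m = shock.gamma, shock.mach
    ratio = 1.0 + (2.0 * g / (g + 1.0)) * (m * m - 1.0)
    p2 = ratio * shock.ambient_pressure_Pa
    return p2, p2 / 1e5


def mach_from_frames(positions_m: Sequence[float], frame_rate_hz: float,
                     temperature_K: float = ROOM_TEMPERATURE_K,
                     gamma: float = AIR_GAMMA,
                     specific_gas_const: float = AIR_SPECIFIC_GAS_CONSTANT,
                     ) -> MachResult:
    """Shock-front Mach number from per-frame front positions.

    The front speed is the least-squares slope of position against frame
    time; the Mach number divides it by the local sound speed
    ``sqrt(gamma R_s T)``.  A result below Mach 1 flags a subsonic
    (non-shock) front via :attr:`MachResult.supersonic`.
    """
    pos = np.asarray(positions_m, dtype=float)
    if pos.size < 2:
        raise ParameterError("need at least 2 front positions")
    if frame_rate_hz <= 0:
        raise ParameterError("frame_rate_hz must be > 0")
    t = np.arange(pos.size) / frame_rate_hz
    speed = float(np.polyfit(t, pos, 1)[0])
    c = sound_speed_air(temperature_K, gamma, specific_gas_const)
    return MachResult(front_speed_m_s=speed, sound_speed_m_s=c, mach=speed / c)


def air_path_delay_change(delta_distance_m: float, speed_m_s: float) -> float:
    """TOF change (s) from a change in the air path, at a given front speed.

    Used to bound the membrane-bulge artifact: a few mm of bulge shortens
    the air path by ``delta / speed`` whether evaluated at the ambient sound
    speed or at the faster shock-front speed.
    """
    if speed_m_s <= 0:
        raise ParameterError("speed_m_s must be > 0")
    return delta_distance_m / speed_m_s


def full_report(spark: SparkSpec | None = None, room: RoomSpec | None = None,
                shock: ShockSpec | None = None) -> dict:
    """The complete safety calculation chain as a plain dict (JSON-ready)."""
    spark = spark or SparkSpec()
    room = room or RoomSpec()
    shock = shock or ShockSpec()
    energy = capacitor_energy(spark)
    ozone = ozone_budget(energy, room)
    p_pa, p_bar = shock_peak_pressure(shock)
    return {
        "capacitor_energy_J": energy,
        "moles_O2_dissociated": ozone.moles_O2_dissociated,
        "moles_O3": ozone.moles_O3,
        "moles_air": ozone.moles_air,
        "ozone_concentration_ppb": ozone.concentration_ppb,
        "shock_mach": shock.mach,
        "shock_peak_pressure_Pa": p_pa,
        "shock_peak_pressure_bar": p_bar,
    }
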