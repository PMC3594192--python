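"""Cantilever calibration: optical-lever sensitivity from the hard-contact
slope, spring constant from the thermal deflection spectrum (equipartition),
and photodiode-signal-to-force conversion."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ROOM_TEMPERATURE_K, thermal_energy
from .curves import ForceCurve

__all__ = [
    "Calibration",
    "fit_sensitivity",
    "fit_spring_constant",
    "to_force",
]


@dataclass
class Calibration:
    """sensitivity in nm per photodiode signal unit (nm/V); spring constant in
    pN/nm; temperature in K."""

    sensitivity: float
    spring_constant: float
    temperature: float = ROOM_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"sensitivity_nm_V={self.sensitivity!r}\n")
            fh.write(f"spring_constant_pN_nm={self.spring_constant!r}\n")
            fh.write(f"temperature_K={self.temperature!r}\n")

    @classmethod
    def load(cls, path) -> "Calibration":
        vals = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                vals[key.strip()] = float(val)
        return cls(
            sensitivity=vals["sensitivity_nm_V"],
            spring_constant=vals["spring_constant_pN_nm"],
            temperature=vals.get("temperature_K", ROOM_TEMPERATURE_K),
        )


def fit_sensitivity(z: np.ndarray, deflection_signal: np.ndarray) -> float:
    """Optical-lever sensitivity from the contact portion of a force plot.

    In hard contact the cantilever deflection follows the piezo one-to-one, so
    the recorded signal is linear in z with slope 1/sensitivity. Returns the
    inverse of the absolute least-squares slope, in nm per signal unit.
    """
    z = np.asarray(z, dtype=float)
    sig = np.asarray(deflection_signal, dtype=float)
    if len(z) < 10:
        raise ValueError("contact segment needs at least 10 points")
    slope = np.polyfit(z, sig, 1)[0]
    span = np.ptp(sig)
    if abs(slope) * np.ptp(z) < 1e-12 or span == 0:
        raise ValueError("no contact slope detected (constant deflection)")
    return 1.0 / abs(slope)


def fit_spring_constant(deflection_series: np.ndarray,
                        temperature: float = ROOM_TEMPERATURE_K) -> float:
    """Spring constant (pN/nm) from a thermal deflection series (nm) by
    equipartition: k = kB·T / Var(deflection), variance after mean removal.

    This is the thermal-tune calibration evaluated in the time domain; for a
    harmonic cantilever the deflection variance equals the integrated thermal
    spectrum, so no line-shape fit is needed.
    """
    x = np.asarray(deflection_series, dtype=float)
    if len(x) < 10_000:
        raise ValueError("need at least 1e4 samples for a stable variance")
    var = float(np.var(x - np.mean(x)))
    if var <= 0:
        raise ValueError("zero-variance deflection series")
    return thermal_energy(temperature) / var


def to_force(raw_curve: ForceCurve, calibration: Calibration) -> ForceCurve:
    """Convert a raw photodiode-signal curve to force in pN.

    force = signal × sensitivity × spring_constant. The calibration used is
    recorded in the curve metadata.
    """
    if calibration is None:
        raise ValueError("calibration required")
    scale = calibration.sensitivity * calibration.spring_constant
    meta = dict(raw_curve.metadata)
    meta.update(
        sensitivity_nm_V=calibration.sensitivity,
        spring_constant_pN_nm=calibration.spring_constant,
        temperature_K=calibration.temperature,
    )
    return ForceCurve(
        curve_id=raw_curve.curve_id,
        z=raw_curve.z.copy(),
        force_approach=raw_curve.force_approach * scale,
        force_retract=raw_curve.force_retract * scale,
        retract_velocity=raw_curve.retract_velocity,
        dwell_time=raw_curve.dwell_time,
        metadata=meta,
    )
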