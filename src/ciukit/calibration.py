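"""Traveling-wave IMS CCS calibration via the corrected power-law protocol.

Measured drift times are EDC-corrected, literature CCS values are
reduced-mass/charge corrected, and a straight line is fitted in log-log
space; the slope is the empirical exponent ``X`` and the intercept gives the
prefactor ``A``.  Applying the model to an analyte inverts the corrections:

    omega = A * td'**X * z / sqrt(mu)

with mu the ion/drift-gas reduced mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: default EDC delay coefficient, ms * (m/z)^(-1/2) scale (instrument-typical)
DEFAULT_EDC_COEFFICIENT = 1.57
#: nitrogen drift-gas mass, Da
N2_MASS = 28.0134
#: helium drift-gas mass, Da
HE_MASS = 4.0026

PROTON_MASS = 1.00728

# Representative literature calibrant entries (He-referenced CCS, nm^2).
# These are editable fixtures: the calibrant proteins are standard
# (denatured myoglobin, native cytochrome c, native ubiquitin) but the exact
# charge states used by any given lab vary, so the table is explicit input,
# not a claim.
DEFAULT_CALIBRANTS: list[dict] = [
    {"name": "ubiquitin+4", "mass": 8565.8, "charge": 4, "ccs_lit": 10.00},
    {"name": "ubiquitin+5", "mass": 8565.8, "charge": 5, "ccs_lit": 11.37},
    {"name": "ubiquitin+6", "mass": 8565.8, "charge": 6, "ccs_lit": 12.30},
    {"name": "cytochrome_c+6", "mass": 12358.0, "charge": 6, "ccs_lit": 12.40},
    {"name": "cytochrome_c+7", "mass": 12358.0, "charge": 7, "ccs_lit": 13.00},
    {"name": "myoglobin_den+9", "mass": 16951.0, "charge": 9, "ccs_lit": 22.60},
    {"name": "myoglobin_den+10", "mass": 16951.0, "charge": 10, "ccs_lit": 24.30},
    {"name": "myoglobin_den+11", "mass": 16951.0, "charge": 11, "ccs_lit": 25.80},
    {"name": "myoglobin_den+12", "mass": 16951.0, "charge": 12, "ccs_lit": 27.20},
]


class CalibrationError(ValueError):
    """Raised for invalid calibration inputs or degenerate fits."""


@dataclass
class CalibrantPoint:
    """One calibrant measurement: identity, literature CCS and drift time."""

    name: str
    mass: float  # Da
    charge: int  # elementary charges
    mz: float  # Th
    ccs_lit: float  # nm^2, He-referenced literature value
    td: float  # ms, measured drift time

    def __post_init__(self) -> None:
        for attr in ("mass", "charge", "mz", "ccs_lit", "td"):
            if getattr(self, attr) <= 0:
                raise CalibrationError(f"{attr} must be positive for {self.name!r}")
        expected_mz = (self.mass + self.charge * PROTON_MASS) / self.charge
        if abs(self.mz - expected_mz) > 0.01 * self.mz:
            raise CalibrationError(
                f"m/z {self.mz} inconsistent with mass/charge for {self.name!r} "
                f"(expected about {expected_mz:.2f})"
            )

    @classmethod
    def from_mass_charge(
        cls, name: str, mass: float, charge: int, ccs_lit: float, td: float
    ) -> "CalibrantPoint":
        mz = (mass + charge * PROTON_MASS) / charge
        return cls(name=name, mass=mass, charge=charge, mz=mz, ccs_lit=ccs_lit, td=td)


@dataclass
class CalibrationModel:
    """Power-law calibration omega' = A * td'**X with bookkeeping for reuse."""

    A: float
    X: float
    edc_coefficient: float = DEFAULT_EDC_COEFFICIENT
    drift_gas_mass: float = N2_MASS
    fit_r2: float = float("nan")
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.A <= 0 or self.X <= 0:
            raise CalibrationError("A and X must be positive")
        if np.isfinite(self.fit_r2) and self.fit_r2 > 1 + 1e-12:
            raise CalibrationError("R^2 cannot exceed 1")


def corrected_drift_time(td: float, mz: float, edc_coefficient: float) -> float:
    """EDC flight-time correction: td' = td - edc * sqrt(mz) / 1000 (ms)."""
    if td <= 0:
        raise CalibrationError("drift time must be positive")
    td_prime = td - edc_coefficient * math.sqrt(mz) / 1000.0
    if td_prime <= 0:
        raise CalibrationError(
            f"flight-time correction exceeds measured drift time ({td} ms)"
        )
    return td_prime


def reduced_mass(mass: float, drift_gas_mass: float) -> float:
    return mass * drift_gas_mass / (mass + drift_gas_mass)


def corrected_literature_ccs(
    ccs_lit: float, charge: int, mass: float, drift_gas_mass: float
) -> float:
    """Charge/reduced-mass corrected CCS: omega' = ccs_lit * sqrt(mu) / z."""
    if min(ccs_lit, charge, mass, drift_gas_mass) <= 0:
        raise CalibrationError("all inputs must be positive")
    mu = reduced_mass(mass, drift_gas_mass)
    return ccs_lit * math.sqrt(mu) / charge


def fit_calibration(
    points: list[CalibrantPoint],
    edc_coefficient: float = DEFAULT_EDC_COEFFICIENT,
    drift_gas_mass: float = N2_MASS,
) -> CalibrationModel:
    """Least-squares line on (ln td', ln omega'): slope X, intercept ln A.

    Requires at least three points with distinct corrected drift times.
    """
    if len(points) < 3:
        raise CalibrationError("need at least 3 calibrant points")
    ln_td = np.array(
        [math.log(corrected_drift_time(p.td, p.mz, edc_coefficient)) for p in points]
    )
    ln_omega = np.array(
        [
            math.log(
                corrected_literature_ccs(p.ccs_lit, p.charge, p.mass, drift_gas_mass)
            )
            for p in points
        ]
    )
    if np.ptp(ln_td) < 1e-12:
        raise CalibrationError("degenerate calibrant spread in corrected drift time")
    slope, intercept = np.polyfit(ln_td, ln_omega, 1)
    predicted = intercept + slope * ln_td
    ss_res = float(np.sum((ln_omega - predicted) ** 2))
    ss_tot = float(np.sum((ln_omega - ln_omega.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    residuals = np.expm1(ln_omega - predicted)  # per-point relative error
    if slope <= 0:
        raise CalibrationError("fitted exponent is non-positive")
    return CalibrationModel(
        A=math.exp(intercept),
        X=float(slope),
        edc_coefficient=edc_coefficient,
        drift_gas_mass=drift_gas_mass,
        fit_r2=r2,
        residuals=residuals,
    )


def calibrated_ccs(
    model: CalibrationModel, td: float, mz: float, charge: int, mass: float
) -> float:
    """Apply the calibration to an analyte drift time -> CCS (nm^2)."""
    td_prime = corrected_drift_time(td, mz, model.edc_coefficient)
    mu = reduced_mass(mass, model.drift_gas_mass)
    return model.A * td_prime**model.X * charge / math.sqrt(mu)


def invert_calibration(
    model: CalibrationModel, ccs: float, mz: float, charge: int, mass: float
) -> float:
    """Drift time (ms) that the model maps to *ccs*; exact inverse of
    :func:`calibrated_ccs`."""
    if ccs <= 0:
        raise CalibrationError("ccs must be positive")
    mu = reduced_mass(mass, model.drift_gas_mass)
    omega_prime = ccs * math.sqrt(mu) / charge
    td_prime = (omega_prime / model.A) ** (1.0 / model.X)
    return td_prime + model.edc_coefficient * math.sqrt(mz) / 1000.0
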