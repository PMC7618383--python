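"""Scalar oxygen-isotope transforms for bioapatite and carbonate paleothermometry.

This module holds the closed-form layer of the proxy system:

* the aragonite carbonate--water thermometer,
  ``T(°C) = 20.6 − 4.34·(δ18Oc[VPDB] − δ18Ow[VSMOW])``;
* the phosphate--water thermometer (recalibrated Kolodny-type equation),
  ``T(°C) = 117.4 − 4.50·(δ18Op[VSMOW] − δ18Ow[VSMOW])``;
* their exact algebraic inverses, used to forward-predict mineral values
  (δ18Oc*, δ18Op*) from water temperature and composition;
* the VPDB→VSMOW scale conversion for carbonates and the
  carbonate→phosphate transfer regression;
* the Southern Ocean δ18Ow--salinity relation; and
* the two-point reference-material calibration applied to raw
  mass-spectrometer measurements.

All δ18O values are plain per-mil decimals (22.0 means 22.0‰). Values carry
scale (VSMOW/VPDB) and substrate (carbonate/phosphate/water) tags through
:class:`DeltaValue`; operations reject a mismatched tag rather than silently
converting. Coefficient uncertainties are stored on the coefficient objects
but are NOT propagated here — the closed-form layer stays exact, and
uncertainty propagation happens only in the Bayesian inversion when enabled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "VSMOW",
    "VPDB",
    "CARBONATE",
    "PHOSPHATE",
    "WATER",
    "DeltaValue",
    "ThermometerCoefficients",
    "TransferCoefficients",
    "SalinityRelation",
    "ReferenceMaterial",
    "CoefficientSet",
    "ScaleError",
    "CalibrationError",
    "ARAGONITE_THERMOMETER",
    "PHOSPHATE_THERMOMETER",
    "TRANSFER",
    "SALINITY_RELATION",
    "USGS80",
    "USGS81",
    "aragonite_temperature",
    "phosphate_temperature",
    "predict_d18Op",
    "predict_d18Oc",
    "vpdb_to_vsmow",
    "carbonate_to_phosphate",
    "salinity_to_d18Ow",
    "d18Ow_shift_from_salinity",
    "two_point_calibrate",
]

VSMOW = "VSMOW"
VPDB = "VPDB"
CARBONATE = "carbonate"
PHOSPHATE = "phosphate"
WATER = "water"

_SCALES = frozenset({VSMOW, VPDB})
_SUBSTRATES = frozenset({CARBONATE, PHOSPHATE, WATER})


class ScaleError(ValueError):
    """A δ18O value carried the wrong scale or substrate tag for an operation."""


class CalibrationError(ValueError):
    """Reference-material calibration is degenerate or ill-posed."""


@dataclass(frozen=True)
class DeltaValue:
    """A δ18O value (‰) tagged with its reference scale and substrate.

    Water and phosphate values are reported on VSMOW only; carbonate values
    carry an explicit VSMOW or VPDB tag.
    """

    value: float
    scale: str
    substrate: str

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ScaleError(f"unknown scale {self.scale!r}")
        if self.substrate not in _SUBSTRATES:
            raise ScaleError(f"unknown substrate {self.substrate!r}")
        if self.substrate in (WATER, PHOSPHATE) and self.scale != VSMOW:
            raise ScaleError(
                f"{self.substrate} values must be VSMOW, got {self.scale!r}"
            )
        if not np.isfinite(self.value):
            raise ValueError(f"non-finite δ18O value: {self.value!r}")

    def require(self, substrate: str, scale: str) -> float:
        if self.substrate != substrate or self.scale != scale:
            raise ScaleError(
                f"expected {substrate} [{scale}], got "
                f"{self.substrate} [{self.scale}]"
            )
        return self.value


def water(value: float) -> DeltaValue:
    """δ18Ow (‰ VSMOW)."""
    return DeltaValue(value, VSMOW, WATER)


def phosphate(value: float) -> DeltaValue:
    """δ18Op (‰ VSMOW)."""
    return DeltaValue(value, VSMOW, PHOSPHATE)


def carbonate_vpdb(value: float) -> DeltaValue:
    """δ18Oc (‰ VPDB)."""
    return DeltaValue(value, VPDB, CARBONATE)


def _as_value(x, substrate: str, scale: str):
    """Accept a tagged DeltaValue (validated) or a bare float/array (trusted).

    Scalar inputs must be finite; in arrays NaN is allowed as the missing
    (land) marker and propagates, but infinities are rejected.
    """
    if isinstance(x, DeltaValue):
        return x.require(substrate, scale)
    out = np.asarray(x, dtype=float)
    if np.any(np.isinf(out)):
        raise ValueError("non-finite δ18O input")
    if out.ndim == 0:
        if np.isnan(out):
            raise ValueError("non-finite δ18O input")
        return float(out)
    return out


@dataclass(frozen=True)
class ThermometerCoefficients:
    """Linear paleothermometer T = intercept − slope·(δ_mineral − δ18Ow)."""

    intercept: float
    slope: float
    intercept_sd: float = 0.0
    slope_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("thermometer slope must be positive")
        if self.intercept_sd < 0 or self.slope_sd < 0:
            raise ValueError("coefficient SDs must be non-negative")

    def temperature(self, d_mineral, d_water):
        return self.intercept - self.slope * (d_mineral - d_water)

    def mineral(self, temperature, d_water):
        return (self.intercept - temperature) / self.slope + d_water


@dataclass(frozen=True)
class TransferCoefficients:
    """Scale/substrate transfer: VPDB→VSMOW map and carbonate→phosphate regression."""

    vpdb_to_vsmow_intercept: float = 30.92
    vpdb_to_vsmow_slope: float = 1.03092
    carb_to_phos_offset: float = 8.67
    carb_to_phos_offset_sd: float = 1.24
    carb_to_phos_slope: float = 1.02
    carb_to_phos_slope_sd: float = 0.06

    def __post_init__(self) -> None:
        if self.vpdb_to_vsmow_slope <= 0 or self.carb_to_phos_slope <= 0:
            raise ValueError("transfer slopes must be positive")


@dataclass(frozen=True)
class SalinityRelation:
    """Linear δ18Ow (‰ VSMOW) vs salinity (PSU): δ18Ow = slope·S + intercept."""

    slope: float = 0.24
    intercept: float = -8.45


@dataclass(frozen=True)
class ReferenceMaterial:
    """A silver-phosphate reference material with its accepted δ18Op."""

    name: str
    accepted_d18Op: float


# Default coefficient values from the published calibrations used throughout.
ARAGONITE_THERMOMETER = ThermometerCoefficients(20.6, 4.34)
PHOSPHATE_THERMOMETER = ThermometerCoefficients(117.4, 4.50, 9.5, 0.43)
TRANSFER = TransferCoefficients()
SALINITY_RELATION = SalinityRelation()
USGS80 = ReferenceMaterial("USGS 80", 13.1)
USGS81 = ReferenceMaterial("USGS 81", 35.4)


@dataclass(frozen=True)
class CoefficientSet:
    """A versioned bundle of all transform coefficients.

    Serializable to/from JSON so alternative calibrations (e.g. a Pucéat-type
    phosphate equation) can be swapped in without touching code.
    """

    version: str = "default-1"
    aragonite: ThermometerCoefficients = ARAGONITE_THERMOMETER
    phosphate: ThermometerCoefficients = PHOSPHATE_THERMOMETER
    transfer: TransferCoefficients = TRANSFER
    salinity: SalinityRelation = SALINITY_RELATION

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CoefficientSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            version=d["version"],
            aragonite=ThermometerCoefficients(**d["aragonite"]),
            phosphate=ThermometerCoefficients(**d["phosphate"]),
            transfer=TransferCoefficients(**d["transfer"]),
            salinity=SalinityRelation(**d["salinity"]),
        )


def aragonite_temperature(d18Oc, d18Ow, coeffs: ThermometerCoefficients = ARAGONITE_THERMOMETER):
    """Formation temperature (°C) from aragonite δ18Oc (VPDB) and δ18Ow (VSMOW)."""
    c = _as_value(d18Oc, CARBONATE, VPDB)
    w = _as_value(d18Ow, WATER, VSMOW)
    return coeffs.temperature(c, w)


def phosphate_temperature(d18Op, d18Ow, coeffs: ThermometerCoefficients = PHOSPHATE_THERMOMETER):
    """Formation temperature (°C) from bioapatite δ18Op and δ18Ow (both VSMOW)."""
    p = _as_value(d18Op, PHOSPHATE, VSMOW)
    w = _as_value(d18Ow, WATER, VSMOW)
    return coeffs.temperature(p, w)


def predict_d18Op(temperature, d18Ow, coeffs: ThermometerCoefficients = PHOSPHATE_THERMOMETER):
    """Forward-predicted δ18Op* (‰ VSMOW): exact inverse of the phosphate thermometer."""
    w = _as_value(d18Ow, WATER, VSMOW)
    return coeffs.mineral(np.asarray(temperature, dtype=float) if np.ndim(temperature) else temperature, w)


def predict_d18Oc(temperature, d18Ow, coeffs: ThermometerCoefficients = ARAGONITE_THERMOMETER):
    """Forward-predicted aragonite δ18Oc* (‰ VPDB): exact inverse of the carbonate thermometer."""
    w = _as_value(d18Ow, WATER, VSMOW)
    return coeffs.mineral(np.asarray(temperature, dtype=float) if np.ndim(temperature) else temperature, w)


def vpdb_to_vsmow(d18Oc, coeffs: TransferCoefficients = TRANSFER):
    """Retag carbonate δ18Oc from the VPDB to the VSMOW scale (affine map)."""
    c = _as_value(d18Oc, CARBONATE, VPDB)
    return coeffs.vpdb_to_vsmow_intercept + coeffs.vpdb_to_vsmow_slope * c


def carbonate_to_phosphate(d18Oc, coeffs: TransferCoefficients = TRANSFER):
    """Transpose carbonate δ18Oc (VPDB) to a phosphate-equivalent δ18Op (VSMOW).

    Chains the VPDB→VSMOW scale conversion with the empirical
    carbonate→phosphate regression δ18Op = (δ18Oc[VSMOW] − offset)/slope.
    """
    c_vsmow = vpdb_to_vsmow(d18Oc, coeffs)
    return (c_vsmow - coeffs.carb_to_phos_offset) / coeffs.carb_to_phos_slope


def salinity_to_d18Ow(salinity, relation: SalinityRelation = SALINITY_RELATION):
    """δ18Ow (‰ VSMOW) from salinity (PSU) via the linear mixing relation."""
    s = np.asarray(salinity, dtype=float)
    if np.any(s < 0):
        raise ValueError("salinity must be non-negative")
    out = relation.slope * s + relation.intercept
    return out if out.ndim else float(out)


def d18Ow_shift_from_salinity(delta_salinity, relation: SalinityRelation = SALINITY_RELATION):
    """Differential form: Δδ18Ow (‰) for a salinity change ΔS (PSU)."""
    out = relation.slope * np.asarray(delta_salinity, dtype=float)
    return out if out.ndim else float(out)


def two_point_calibrate(
    raw: Sequence[float],
    ref_measured: Sequence[float],
    refs: Sequence[ReferenceMaterial] = (USGS80, USGS81),
    drift_order: Sequence[int] | None = None,
    ref_order: Sequence[float] | None = None,
) -> np.ndarray:
    """Two-point calibration of raw δ18Op measurements to the VSMOW scale.

    Fits the line mapping the two measured reference values onto their
    accepted values and applies it to ``raw``. Applying the fitted map to the
    reference measurements returns the accepted values exactly.

    An optional drift correction (off by default) linearly detrends
    reference-material residuals against analysis order before calibrating:
    pass ``ref_order`` (analysis positions of every reference replicate,
    with ``ref_measured`` then holding one measured value per replicate and
    ``refs`` repeated accordingly is NOT required — see below) via the
    simpler hook ``drift_order`` giving the analysis positions of ``raw``.

    Parameters
    ----------
    raw : sequence of ‰ values to calibrate.
    ref_measured : the two measured values of the reference materials,
        in the same order as ``refs``.
    refs : the two reference materials (default USGS 80 / USGS 81).
    drift_order, ref_order : optional analysis-order positions of the raw
        and reference measurements; when both are given, a linear drift of
        the mean reference residual versus order is removed from ``raw``
        before the two-point map is applied.
    """
    if len(refs) != 2:
        raise CalibrationError("exactly two reference materials required")
    a1, a2 = refs[0].accepted_d18Op, refs[1].accepted_d18Op
    if a1 == a2:
        raise CalibrationError("reference materials must have distinct accepted values")
    m = np.asarray(ref_measured, dtype=float)
    if m.shape != (2,):
        raise CalibrationError("ref_measured must hold exactly two values")
    m1, m2 = m
    if m1 == m2:
        raise CalibrationError("coincident reference measurements: calibration is degenerate")

    x = np.asarray(raw, dtype=float).copy()

    if drift_order is not None and ref_order is not None:
        # Linear drift model fitted to the two reference residuals vs analysis
        # order, removed from the raw values at their own positions. After the
        # correction the reference residuals vanish, so the two-point map
        # reduces to the identity in measured space.
        resid = np.array([m1 - a1, m2 - a2])
        ro = np.asarray(ref_order, dtype=float)
        if ro.shape != (2,) or ro[0] == ro[1]:
            raise CalibrationError("ref_order must hold two distinct positions")
        dslope = (resid[1] - resid[0]) / (ro[1] - ro[0])
        dintercept = resid[0] - dslope * ro[0]
        x = x - (dintercept + dslope * np.asarray(drift_order, dtype=float))
        m1, m2 = a1, a2

    slope = (a2 - a1) / (m2 - m1)
    intercept = a1 - slope * m1
    return intercept + slope * x
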