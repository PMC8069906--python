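"""Soil-profile types and water/energy conversion helpers.

The irrigation model reasons about three sensed depths (30, 60, 90 cm) of a
layered profile.  Each layer carries the agronomic water constants used both
to judge the moisture status of the crop and, at prediction time, to replace
observed soil moisture with field capacity:

* **FC** (field capacity, %): moisture held after free drainage; above it
  water percolates to the subsoil and is lost to the crop.
* **WP** (wilting point, %): moisture below which the plant cannot extract
  water.
* **AWC** (available water capacity, %): FC − WP, the water the crop can use;
  the management band for the crop is AWC ≤ moisture ≤ FC.

Irrigation depth and pumping energy are linked by a fixed conversion: one
conventional daily dose of water corresponds to a known pump consumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

__all__ = [
    "SoilLayer",
    "SoilProfile",
    "ConversionConstants",
    "DEFAULT_SOIL_PROFILE",
    "DEFAULT_CONSTANTS",
    "awc_from_fc_wp",
    "moisture_status",
    "mm_to_kwh",
    "kwh_to_mm",
]

#: tolerance (percent points) when checking a printed AWC against FC − WP
AWC_ROUNDING_TOL = 0.05


def awc_from_fc_wp(fc: float, wp: float) -> float:
    """Available water capacity (%) from field capacity and wilting point.

    Parameters
    ----------
    fc, wp : float
        Field capacity and wilting point, volumetric %.  Requires
        ``fc >= wp >= 0``.
    """
    if wp < 0:
        raise ValueError(f"wilting point must be non-negative, got {wp}")
    if fc < wp:
        raise ValueError(f"field capacity {fc} < wilting point {wp}")
    return fc - wp


@dataclass(frozen=True)
class SoilLayer:
    """One sensed depth of the soil profile with its water constants."""

    depth_cm: int
    texture: str = "sandy loam"
    om: float = 0.0          # organic matter, %
    fc: float = 0.0          # field capacity, %
    wp: float = 0.0          # wilting point, %
    awc: float | None = None  # available water capacity, %; defaults to fc - wp
    density: float | None = None   # stored verbatim from soil reports; unused
    limestone: float | None = None  # total limestone g/kg; unused

    def __post_init__(self) -> None:
        for name in ("om", "fc", "wp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.fc <= self.wp:
            raise ValueError(
                f"field capacity ({self.fc}) must exceed wilting point ({self.wp})"
            )
        if self.awc is None:
            object.__setattr__(self, "awc", awc_from_fc_wp(self.fc, self.wp))
        elif abs(self.awc - (self.fc - self.wp)) > AWC_ROUNDING_TOL:
            raise ValueError(
                f"awc={self.awc} inconsistent with fc-wp={self.fc - self.wp:.2f}"
            )


@dataclass(frozen=True)
class SoilProfile:
    """Ordered stack of :class:`SoilLayer`, shallowest first."""

    layers: tuple[SoilLayer, ...]

    def __post_init__(self) -> None:
        depths = [l.depth_cm for l in self.layers]
        if len(set(depths)) != len(depths):
            raise ValueError(f"duplicate depths in profile: {depths}")
        if depths != sorted(depths):
            object.__setattr__(
                self, "layers", tuple(sorted(self.layers, key=lambda l: l.depth_cm))
            )

    @property
    def depths(self) -> tuple[int, ...]:
        return tuple(l.depth_cm for l in self.layers)

    def layer(self, depth_cm: int) -> SoilLayer:
        for l in self.layers:
            if l.depth_cm == depth_cm:
                return l
        raise KeyError(f"no layer at {depth_cm} cm (profile has {self.depths})")

    def fc_by_depth(self) -> dict[int, float]:
        return {l.depth_cm: l.fc for l in self.layers}

    @classmethod
    def from_layers(cls, layers: Iterable[SoilLayer]) -> "SoilProfile":
        return cls(tuple(layers))


MoistureStatus = Literal["below", "optimal", "above"]


def moisture_status(moisture: float, layer: SoilLayer) -> MoistureStatus:
    """Classify a moisture reading against the layer's management band.

    The crop optimum lies between the available water capacity and field
    capacity (both bounds closed); above FC water is dispersed into the
    subsoil, below AWC the crop is under-supplied.
    """
    if moisture < 0:
        raise ValueError(f"moisture must be non-negative, got {moisture}")
    if moisture < layer.awc:
        return "below"
    if moisture > layer.fc:
        return "above"
    return "optimal"


@dataclass(frozen=True)
class ConversionConstants:
    """Water-depth ↔ pumping-energy conversion.

    ``dose_mm`` is the water depth of one conventional daily irrigation run
    (1 h of pumping) and ``dose_kwh`` the energy that run consumes; the
    conversion is linear through the origin.
    """

    dose_mm: float = 5.25
    dose_kwh: float = 900.0

    def __post_init__(self) -> None:
        if self.dose_mm <= 0 or self.dose_kwh <= 0:
            raise ValueError("conversion constants must be positive")


DEFAULT_CONSTANTS = ConversionConstants()


def mm_to_kwh(mm: float, constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Convert an irrigation water depth (mm) to pumping energy (kWh)."""
    if mm < 0:
        raise ValueError(f"water depth must be non-negative, got {mm}")
    return mm * constants.dose_kwh / constants.dose_mm


def kwh_to_mm(kwh: float, constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Inverse of :func:`mm_to_kwh`."""
    if kwh < 0:
        raise ValueError(f"energy must be non-negative, got {kwh}")
    return kwh * constants.dose_mm / constants.dose_kwh


#: Sandy-loam apple-orchard profile (alpine valley site) used as the package
#: default: per-depth organic matter, FC, WP and AWC from laboratory soil
#: analysis.  The density column of such reports is stored verbatim but never
#: used in computation (the printed values are physically implausible).
DEFAULT_SOIL_PROFILE = SoilProfile(
    (
        SoilLayer(30, "sandy loam", om=1.6, fc=17.1, wp=6.3, awc=10.8,
                  density=20.54, limestone=10.0),
        SoilLayer(60, "sandy loam", om=1.4, fc=21.6, wp=11.8, awc=9.8,
                  density=34.56, limestone=10.0),
        SoilLayer(90, "sandy loam", om=0.8, fc=16.0, wp=4.1, awc=11.9,
                  density=18.81, limestone=10.0),
    )
)
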