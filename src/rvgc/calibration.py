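"""Optic-disc based image calibration and measurement-zone geometry.

Fundus photographs carry no absolute scale: the number of microns imaged
per pixel depends on camera optics, field of view and (for scanned film)
scanning resolution.  Vessel-assessment practice recovers an approximate
scale from the optic disc (OD), whose average adult diameter is taken to
be 1800 um.  The resulting image conversion factor (ICF, um per pixel)
comes in two flavours:

* a *constant* ICF, ``reference / mean cohort OD diameter``, shared by
  every image of a cohort, and
* an *individual* ICF, ``reference / this eye's OD diameter``, recomputed
  per image.

The ICF does double duty: it converts pixel calibers to um, and it fixes
the pixel radii of the concentric measurement zones around the disc.
Zone B covers 0.5-1.0 OD diameters from the disc margin and zone C covers
0.5-2.0 (equivalently 1.0-1.5 and 1.0-2.5 OD diameters from the disc
center), i.e. 1800-2700 um and 1800-4500 um against the reference disc.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np

#: Reference optic-disc diameter in microns (1850 is also found in the
#: literature; every entry point takes it as a keyword).
REFERENCE_OD_UM = 1800.0


class CalibrationError(ValueError):
    """Invalid disc geometry or conversion-factor arithmetic."""


@dataclass(frozen=True)
class OpticDisc:
    """Optic-disc location and extent, in pixels of a particular image."""

    center: Tuple[float, float]
    h_diameter_px: float
    v_diameter_px: float

    def __post_init__(self) -> None:
        if self.h_diameter_px <= 0 or self.v_diameter_px <= 0:
            raise CalibrationError("optic-disc diameters must be positive")

    @property
    def mean_diameter_px(self) -> float:
        return (self.h_diameter_px + self.v_diameter_px) / 2.0


@dataclass(frozen=True)
class ConversionFactor:
    """A um-per-pixel scale with provenance.

    ``kind`` records whether the denominator was the cohort-average disc
    ("constant") or the analyzed eye's own disc ("individual").
    """

    value: float
    kind: str
    reference_od_um: float = REFERENCE_OD_UM

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise CalibrationError("conversion factor must be positive")
        if self.kind not in ("constant", "individual"):
            raise CalibrationError(f"unknown ICF kind: {self.kind!r}")

    @property
    def od_px(self) -> float:
        """The disc diameter in pixels implied by this factor."""
        return self.reference_od_um / self.value


@dataclass(frozen=True)
class MeasurementZones:
    """Concentric annuli around the disc center, radii in pixels."""

    center: Tuple[float, float]
    zone_b: Tuple[float, float]
    zone_c: Tuple[float, float]

    def __post_init__(self) -> None:
        if not (0 < self.zone_b[0] < self.zone_b[1] < self.zone_c[1]):
            raise CalibrationError("zone radii must be positive and ordered")
        if self.zone_b[0] != self.zone_c[0]:
            raise CalibrationError("zones B and C share the inner radius")


def mean_od_diameter(disc: OpticDisc) -> float:
    """Mean of the horizontal and vertical disc diameters, px."""
    return disc.mean_diameter_px


def individual_icf(od_px: float, reference_od_um: float = REFERENCE_OD_UM) -> ConversionFactor:
    """ICF of a single eye: ``reference_od_um / od_px`` um per pixel."""
    if od_px <= 0:
        raise CalibrationError("OD diameter must be positive")
    return ConversionFactor(reference_od_um / od_px, "individual", reference_od_um)


def constant_icf(
    cohort_od_px: Iterable[float], reference_od_um: float = REFERENCE_OD_UM
) -> ConversionFactor:
    """Cohort-level ICF: ``reference_od_um / mean(cohort OD diameters)``."""
    ods = np.asarray(list(cohort_od_px), dtype=float)
    if ods.size == 0:
        raise CalibrationError("cohort of OD diameters is empty")
    if np.any(ods <= 0):
        raise CalibrationError("OD diameters must be positive")
    return ConversionFactor(reference_od_um / float(ods.mean()), "constant", reference_od_um)


def px_to_um(length_px: float, icf: ConversionFactor) -> float:
    """Convert a pixel length to microns: ``length_um = icf * length_px``."""
    if np.any(np.asarray(length_px) < 0):
        raise CalibrationError("lengths must be non-negative")
    return length_px * icf.value


# Zone boundaries in units of the reference OD diameter, measured as radii
# from the disc center: margin (0.5 diameter) plus 0.5 / 1.0 / 2.0.
_ZONE_INNER_OD = 1.0
_ZONE_B_OUTER_OD = 1.5
_ZONE_C_OUTER_OD = 2.5


def build_zones(disc_center: Tuple[float, float], icf: ConversionFactor) -> MeasurementZones:
    """Measurement annuli implied by an ICF, anchored at ``disc_center``.

    Boundary radii are fixed in microns against the reference disc
    (inner 1.0, zone-B outer 1.5, zone-C outer 2.5 reference diameters)
    and divided by the ICF to obtain pixels.  With an individual ICF the
    inner radius therefore equals the eye's own measured OD diameter;
    with a constant ICF every image gets the same pixel annuli.
    """
    ref = icf.reference_od_um
    r_in = _ZONE_INNER_OD * ref / icf.value
    r_b = _ZONE_B_OUTER_OD * ref / icf.value
    r_c = _ZONE_C_OUTER_OD * ref / icf.value
    return MeasurementZones(tuple(disc_center), (r_in, r_b), (r_in, r_c))
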