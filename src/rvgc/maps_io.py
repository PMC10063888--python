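"""Labeled vessel-map container and lossless PNG + JSON sidecar round-trip.

A vessel map is a single-channel 8-bit label raster with the codes
``0 background, 1 artery, 2 vein, 3 optic disc`` plus a JSON metadata
sidecar describing how the view was framed (centering, field of view,
resampling factor) and where the optic disc sits in the raster.  The
disc geometry in the sidecar is the scale reference for everything
downstream: the image conversion factor and the measurement zones are
derived from it, never from the raster itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict

import numpy as np
from PIL import Image

LABEL_BACKGROUND = 0
LABEL_ARTERY = 1
LABEL_VEIN = 2
LABEL_DISC = 3
VALID_LABELS = frozenset({LABEL_BACKGROUND, LABEL_ARTERY, LABEL_VEIN, LABEL_DISC})

#: Metadata keys every sidecar must carry.
REQUIRED_META_KEYS = (
    "centering",
    "fov_deg",
    "scale_factor",
    "od_center",
    "od_h_diameter_px",
    "od_v_diameter_px",
    "seed",
)


class VesselMapFormatError(ValueError):
    """Raised for unknown label codes or missing/invalid metadata."""


@dataclass
class VesselMap:
    """Label raster plus view metadata.

    ``labels`` is indexed ``[row, col]``; metadata coordinates such as
    ``od_center`` are ``(x, y) == (col, row)`` pixel positions.
    """

    labels: np.ndarray
    meta: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        validate_vessel_map(self)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def od_center(self) -> tuple:
        return tuple(self.meta["od_center"])

    @property
    def od_mean_diameter_px(self) -> float:
        return (self.meta["od_h_diameter_px"] + self.meta["od_v_diameter_px"]) / 2.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VesselMap):
            return NotImplemented
        return np.array_equal(self.labels, other.labels) and self.meta == other.meta


def validate_vessel_map(vmap: VesselMap) -> None:
    present = np.unique(vmap.labels)
    unknown = set(int(v) for v in present) - VALID_LABELS
    if unknown:
        raise VesselMapFormatError(f"unknown label codes present: {sorted(unknown)}")
    missing = [k for k in REQUIRED_META_KEYS if k not in vmap.meta]
    if missing:
        raise VesselMapFormatError(f"metadata missing required keys: {missing}")
    if vmap.meta["centering"] not in ("ODC", "MC"):
        raise VesselMapFormatError(f"unknown centering: {vmap.meta['centering']!r}")


def write_vessel_map(vmap: VesselMap, path) -> Path:
    """Write ``<path>.png`` (8-bit, lossless) and ``<path>.json``.

    Returns the PNG path.  ``path`` may or may not carry the ``.png``
    suffix already.
    """
    validate_vessel_map(vmap)
    png = Path(path)
    if png.suffix.lower() not in (".png", ".tif", ".tiff"):
        png = png.with_suffix(".png")
    png.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(vmap.labels, mode="L").save(png)
    sidecar = png.with_suffix(".json")
    sidecar.write_text(json.dumps(vmap.meta, sort_keys=True, indent=1))
    return png


def read_vessel_map(path) -> VesselMap:
    """Read a label raster and its JSON sidecar back into a :class:`VesselMap`."""
    png = Path(path)
    if not png.exists() and png.suffix == "":
        png = png.with_suffix(".png")
    labels = np.asarray(Image.open(png), dtype=np.uint8)
    sidecar = png.with_suffix(".json")
    if not sidecar.exists():
        raise VesselMapFormatError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    return VesselMap(labels, meta)


def mirror_vessel_map(vmap: VesselMap) -> VesselMap:
    """Horizontally mirror a map, e.g. to model the fellow eye.

    Flips the raster left-right, reflects the metadata x coordinates and
    toggles the ``laterality`` tag (``OD`` right eye / ``OS`` left eye).
    Measurement routines canonicalize on laterality, so a mirrored copy
    of a map yields identical characteristics.
    """
    w = vmap.labels.shape[1]
    meta = dict(vmap.meta)
    cx, cy = vmap.meta["od_center"]
    meta["od_center"] = [w - 1.0 - cx, cy]
    meta["laterality"] = "OS" if vmap.meta.get("laterality", "OD") == "OD" else "OD"
    if "vessels" in meta:
        meta["vessels"] = [
            {**v, "angle_deg": (180.0 - v["angle_deg"]) % 360.0} for v in meta["vessels"]
        ]
    return VesselMap(vmap.labels[:, ::-1].copy(), meta)
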