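"""Ground-truthed synthetic fundus vasculature.

The generator builds an eye as a set of vessels radiating from the optic
disc, each with a known caliber in microns, and renders it as a labeled
raster under a chosen centering (optic-disc-centered or macula-centered),
field of view and resampling factor.  It emulates the statistical
structure of 60-degree fundus photography of a screening cohort:

* disc diameters vary between eyes (default 1800 +/- 135 um, i.e. a
  coefficient of variation of 7.5%, which at the native scale of
  2.4 um/px reproduces an individual-ICF spread of about 2.4 +/- 0.18);
* seven arterioles and seven venules alternate around the disc, with
  arteriolar calibers stochastically narrower than venular ones so the
  arteriovenous ratio falls below 1;
* centerlines are radial rays with a sinusoidal perpendicular
  perturbation giving mild, controllable tortuosity.

Vessels occupy disjoint angular sectors, so rendered vessels never cross
and every raster component maps to exactly one ground-truth vessel.
Rendering is geometric: labels only, no photometric model.  Resolution
changes are modeled by nearest-neighbour resampling of the native
render, mimicking a rescan of the same frame at a different pitch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .maps_io import LABEL_ARTERY, LABEL_DISC, LABEL_VEIN, VesselMap

__all__ = [
    "GenerationParams",
    "GroundTruthVessel",
    "SyntheticEye",
    "ViewSpec",
    "generate_eye",
    "perturb_widths",
    "render_view",
    "RenderError",
]

#: Apparent angular diameter of the optic disc: a 60-degree frame is
#: about 11 disc diameters wide.  Used to translate fov_deg into pixels.
OD_ANGULAR_DEG = 5.5

#: Fovea sits 2.5 disc diameters temporal to the disc center on the
#: horizontal meridian (temporal = +x in the canonical right-eye frame).
FOVEA_OFFSET_OD = 2.5


class RenderError(ValueError):
    """Requested view cannot contain the mandatory measurement region."""


class ParameterError(ValueError):
    """Invalid generation parameters."""


@dataclass(frozen=True)
class GenerationParams:
    """Cohort-level generative settings (units noted per field)."""

    n_arteries: int = 7
    n_veins: int = 7
    od_diameter_um_mean: float = 1800.0
    od_diameter_um_sd: float = 135.0
    true_scale_um_per_px: float = 2.4
    artery_width_um: Tuple[float, float] = (92.0, 10.0)   # mean, sd
    vein_width_um: Tuple[float, float] = (100.0, 12.0)    # mean, sd
    min_width_um: float = 55.0
    wavelength_px: Tuple[float, float] = (250.0, 450.0)   # uniform range
    amplitude_frac: Tuple[float, float] = (0.05, 0.10)    # amplitude / wavelength
    taper_per_od: float = 0.0   # fractional width loss per OD diameter of radial distance
    ellipticity_max: float = 0.03
    reference_od_um: float = 1800.0

    def validate(self) -> None:
        if self.n_arteries < 6 or self.n_veins < 6:
            raise ParameterError("at least six vessels per type are required")
        for name in ("od_diameter_um_mean", "true_scale_um_per_px", "min_width_um"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.od_diameter_um_sd < 0 or self.taper_per_od < 0:
            raise ParameterError("spread/taper parameters must be non-negative")
        for name in ("artery_width_um", "vein_width_um", "wavelength_px"):
            if getattr(self, name)[0] <= 0:
                raise ParameterError(f"{name} must be positive")
        if not (0 <= self.amplitude_frac[0] <= self.amplitude_frac[1]):
            raise ParameterError("amplitude_frac range must be ordered and non-negative")


@dataclass
class GroundTruthVessel:
    vessel_id: int
    vessel_type: str                 # "artery" | "vein"
    centerline: np.ndarray           # (n, 2) scene px, ordered disc -> periphery
    width_um: float                  # caliber at the vessel root
    tortuosity_amplitude: float      # px
    tortuosity_wavelength: float     # px
    angle_deg: float                 # ray direction
    taper_per_od: float = 0.0

    def width_um_at(self, radius_px: np.ndarray, od_px: float) -> np.ndarray:
        """Caliber profile: constant by default, linear taper if enabled."""
        r0 = float(np.hypot(*self.centerline[0]))
        frac = 1.0 - self.taper_per_od * np.maximum(0.0, (radius_px - r0)) / od_px
        return self.width_um * np.maximum(0.2, frac)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["centerline"] = np.asarray(self.centerline).tolist()
        return d


@dataclass
class SyntheticEye:
    true_scale: float                 # um per native px
    od_center: Tuple[float, float]    # scene coordinates (native px)
    od_diameter_um: float
    od_h_diameter_px: float
    od_v_diameter_px: float
    vessels: List[GroundTruthVessel]
    seed: int
    params: GenerationParams = field(default_factory=GenerationParams)

    @property
    def od_diameter_px(self) -> float:
        return self.od_diameter_um / self.true_scale

    def to_json(self) -> str:
        d = {
            "true_scale": self.true_scale,
            "od_center": list(self.od_center),
            "od_diameter_um": self.od_diameter_um,
            "od_h_diameter_px": self.od_h_diameter_px,
            "od_v_diameter_px": self.od_v_diameter_px,
            "seed": self.seed,
            "params": asdict(self.params),
            "vessels": [v.to_dict() for v in self.vessels],
        }
        return json.dumps(d, sort_keys=True)


@dataclass(frozen=True)
class ViewSpec:
    """How an eye is framed and sampled when rendered."""

    centering: str = "ODC"            # "ODC" | "MC"
    fov_deg: float = 60.0
    output_size: Optional[Tuple[int, int]] = None   # (width, height) px
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.centering not in ("ODC", "MC"):
            raise ParameterError(f"unknown centering: {self.centering!r}")
        if self.scale_factor <= 0 or self.fov_deg <= 0:
            raise ParameterError("scale_factor and fov_deg must be positive")


def generate_eye(params: GenerationParams = GenerationParams(), seed: int = 0) -> SyntheticEye:
    """Draw one eye from the cohort distributions; fully seed-determined."""
    params.validate()
    rng = np.random.default_rng(seed)

    sd = params.od_diameter_um_sd
    od_um = float(np.clip(
        rng.normal(params.od_diameter_um_mean, sd),
        params.od_diameter_um_mean - 3 * sd,
        params.od_diameter_um_mean + 3 * sd,
    ))
    od_px = od_um / params.true_scale_um_per_px
    ell = rng.uniform(0.0, params.ellipticity_max)
    od_h_px = od_px * (1.0 + ell)
    od_v_px = od_px * (2.0 - (1.0 + ell))  # mean of h and v equals od_px exactly

    n_total = params.n_arteries + params.n_veins
    rot = rng.uniform(0.0, 2 * np.pi)
    half_sector = np.pi / n_total

    # Vessels must span from inside the disc margin out past zone C for
    # both the individual annulus (2.5 OD diameters) and a cohort-typical
    # constant annulus (2.5 reference diameters).
    ref_px = params.reference_od_um / params.true_scale_um_per_px
    r_start = 0.45 * od_px
    r_end = 2.75 * max(od_px, ref_px)

    # Interleave types around the disc; sector k at angle rot + 2*pi*k/n.
    types = []
    a_left, v_left = params.n_arteries, params.n_veins
    for k in range(n_total):
        if (k % 2 == 0 and a_left > 0) or v_left == 0:
            types.append("artery"); a_left -= 1
        else:
            types.append("vein"); v_left -= 1

    vessels: List[GroundTruthVessel] = []
    for k, vtype in enumerate(types):
        mean_w, sd_w = params.artery_width_um if vtype == "artery" else params.vein_width_um
        width_um = float(max(params.min_width_um, rng.normal(mean_w, sd_w)))
        wavelength = float(rng.uniform(*params.wavelength_px))
        amp = float(rng.uniform(*params.amplitude_frac)) * wavelength
        # Cap the lateral excursion so neighbouring sectors never overlap.
        w_px_half = width_um / params.true_scale_um_per_px / 2.0
        avail = r_start * np.sin(half_sector) - w_px_half - 4.0
        amp = float(np.clip(amp, 0.0, max(0.0, avail)))

        theta = rot + 2 * np.pi * k / n_total
        u = np.array([np.cos(theta), np.sin(theta)])
        n_hat = np.array([-np.sin(theta), np.cos(theta)])
        r = np.arange(r_start, r_end, 0.5)
        offset = amp * np.sin(2 * np.pi * (r - r_start) / wavelength)
        centerline = r[:, None] * u[None, :] + offset[:, None] * n_hat[None, :]
        vessels.append(GroundTruthVessel(
            vessel_id=k,
            vessel_type=vtype,
            centerline=centerline,
            width_um=width_um,
            tortuosity_amplitude=amp,
            tortuosity_wavelength=wavelength,
            angle_deg=float(np.degrees(theta) % 360.0),
            taper_per_od=params.taper_per_od,
        ))

    return SyntheticEye(
        true_scale=params.true_scale_um_per_px,
        od_center=(0.0, 0.0),
        od_diameter_um=od_um,
        od_h_diameter_px=od_h_px,
        od_v_diameter_px=od_v_px,
        vessels=vessels,
        seed=seed,
        params=params,
    )


def perturb_widths(eye: SyntheticEye, sigma_um: float, seed: int) -> SyntheticEye:
    """Independent caliber noise, e.g. biological left/right variation."""
    if sigma_um == 0:
        return eye
    rng = np.random.default_rng(seed)
    vessels = []
    for v in eye.vessels:
        w = float(max(eye.params.min_width_um, v.width_um + rng.normal(0.0, sigma_um)))
        vessels.append(GroundTruthVessel(
            v.vessel_id, v.vessel_type, v.centerline, w,
            v.tortuosity_amplitude, v.tortuosity_wavelength, v.angle_deg, v.taper_per_od,
        ))
    return SyntheticEye(
        eye.true_scale, eye.od_center, eye.od_diameter_um,
        eye.od_h_diameter_px, eye.od_v_diameter_px, vessels, eye.seed, eye.params,
    )


def _default_extent(eye: SyntheticEye, view: ViewSpec) -> Tuple[float, float]:
    """Native (width, height) of the minimal frame containing zone C."""
    ref_px = eye.params.reference_od_um / eye.true_scale
    half = 2.75 * max(eye.od_diameter_px, ref_px) + 8.0
    if view.centering == "ODC":
        w = h = 2.0 * half
    else:
        w = 2.0 * (FOVEA_OFFSET_OD * eye.od_diameter_px + half)
        h = 2.0 * half
    fov_px = view.fov_deg * eye.od_diameter_px / OD_ANGULAR_DEG
    return min(w, fov_px), min(h, fov_px)


def render_view(eye: SyntheticEye, view: ViewSpec = ViewSpec()) -> VesselMap:
    """Rasterize an eye as a labeled vessel map under the given view.

    The scene is first rasterized at the eye's native scale in a frame
    centered on the disc (ODC) or the fovea (MC); ``scale_factor != 1``
    then resamples that native render with nearest-neighbour
    interpolation, and the sidecar metadata records the disc geometry as
    rendered.
    """
    od_px = eye.od_diameter_px
    cx, cy = eye.od_center
    if view.centering == "MC":
        cx, cy = cx + FOVEA_OFFSET_OD * od_px, cy

    s = view.scale_factor
    if view.output_size is not None:
        wn, hn = view.output_size[0] / s, view.output_size[1] / s
    else:
        wn, hn = _default_extent(eye, view)
    width_n, height_n = int(round(wn)), int(round(hn))

    # Zone B (1.5 OD-diameter radius around the disc) must be inside.
    dx = abs(eye.od_center[0] - cx)
    need = 1.5 * od_px + 2.0
    if width_n / 2.0 - dx < need or height_n / 2.0 < need:
        raise RenderError(
            f"output frame {width_n}x{height_n} native px cannot contain zone B "
            f"(needs {need:.0f} px around the disc center)"
        )

    x0 = cx - width_n / 2.0
    y0 = cy - height_n / 2.0
    labels = np.zeros((height_n, width_n), dtype=np.uint8)

    rr, cc = draw_ellipse(
        eye.od_center[1] - y0, eye.od_center[0] - x0,
        eye.od_v_diameter_px / 2.0, eye.od_h_diameter_px / 2.0,
        shape=labels.shape,
    )
    labels[rr, cc] = LABEL_DISC

    for v in eye.vessels:
        pts = v.centerline[::4]  # ~2 px spacing is ample for band polygons
        radius = np.hypot(pts[:, 0] - eye.od_center[0], pts[:, 1] - eye.od_center[1])
        half_w = v.width_um_at(radius, od_px) / eye.true_scale / 2.0
        tang = np.gradient(pts, axis=0)
        tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
        nrm = np.column_stack([-tang[:, 1], tang[:, 0]])
        left = pts + nrm * half_w[:, None]
        right = pts - nrm * half_w[:, None]
        code = LABEL_ARTERY if v.vessel_type == "artery" else LABEL_VEIN
        # Fill the band in short overlapping quad strips: scanline polygon
        # fill costs bbox_area * n_vertices, so one polygon for a long
        # diagonal vessel would be quadratically slow.
        step = 16
        for i0 in range(0, len(pts) - 1, step):
            i1 = min(i0 + step, len(pts) - 1)
            poly = np.vstack([left[i0:i1 + 1], right[i0:i1 + 1][::-1]])
            rr, cc = draw_polygon(poly[:, 1] - y0, poly[:, 0] - x0, shape=labels.shape)
            labels[rr, cc] = code

    if s != 1.0:
        labels = ndi.zoom(labels, s, order=0, prefilter=False)
    shift_x = shift_y = 0.0
    if view.output_size is not None:
        labels, (shift_x, shift_y) = _fit_to(labels, view.output_size)

    meta = {
        "centering": view.centering,
        "fov_deg": view.fov_deg,
        "scale_factor": s,
        "od_center": [
            (eye.od_center[0] - x0) * s + shift_x,
            (eye.od_center[1] - y0) * s + shift_y,
        ],
        "od_h_diameter_px": eye.od_h_diameter_px * s,
        "od_v_diameter_px": eye.od_v_diameter_px * s,
        "seed": eye.seed,
        "laterality": "OD",
        "true_scale_um_per_px": eye.true_scale,
        "vessels": [
            {
                "id": v.vessel_id,
                "type": v.vessel_type,
                "angle_deg": v.angle_deg,
                "width_um": v.width_um,
            }
            for v in eye.vessels
        ],
    }
    return VesselMap(labels, meta)


def _fit_to(labels: np.ndarray, size: Tuple[int, int]):
    """Center-crop/pad a raster to exactly (width, height).

    Returns the fitted raster and the (x, y) shift that maps old pixel
    coordinates to new ones.
    """
    w, h = int(size[0]), int(size[1])
    out = np.zeros((h, w), dtype=labels.dtype)
    ih, iw = labels.shape
    # source and destination windows share the frame center
    sy = max(0, (ih - h) // 2); dy = max(0, (h - ih) // 2)
    sx = max(0, (iw - w) // 2); dx = max(0, (w - iw) // 2)
    ch = min(h, ih); cw = min(w, iw)
    out[dy:dy + ch, dx:dx + cw] = labels[sy:sy + ch, sx:sx + cw]
    return out, (float(dx - sx), float(dy - sy))
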