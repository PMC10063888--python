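"""Cohort-level experiments comparing calibration and centering choices.

Three paired analyses on a synthetic (or user-supplied) cohort:

1. *laterality* - right vs. mirrored fellow eye, constant ICF: a null
   comparison that should stay non-significant;
2. *icf* - the same optic-disc-centered images measured under the
   individual and the constant conversion factor, Bland-Altman style;
3. *centering* - optic-disc- vs. macula-centered views of the same eye,
   individual ICF, with the same vessels selected in both views.

Each run is fully determined by (config, seed) and can write per-image
RVGC tables, agreement tables shaped like the usual Bland-Altman
reports, and a JSON-lines log of per-image quality flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .agreement import PairedSeries, bland_altman, bonferroni_threshold, paired_compare
from .calibration import OpticDisc, constant_icf, individual_icf, mean_od_diameter
from .maps_io import VesselMap, mirror_vessel_map
from .metrics import RVGC_NAMES, MeasurementError, compute_rvgc
from .synthetic_fundus import (
    GenerationParams,
    ViewSpec,
    generate_eye,
    perturb_widths,
    render_view,
)

__all__ = [
    "ExperimentConfig",
    "ConfigError",
    "load_config",
    "run_icf_comparison",
    "run_centering_comparison",
    "run_laterality_comparison",
]


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    n_eyes: int = 20
    seed: int = 0
    icf_modes: Tuple[str, ...] = ("constant", "individual")
    views: Tuple[str, ...] = ("ODC",)
    scale_factors: Tuple[float, ...] = (1.0,)
    fov_deg: float = 60.0
    out_dir: Optional[str] = None
    reference_od_um: float = 1800.0
    max_clip_fraction: float = 0.02
    laterality_noise_um: float = 2.0
    alpha: float = 0.05
    generation: GenerationParams = field(default_factory=GenerationParams)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            (isinstance(self.n_eyes, int) and self.n_eyes >= 3, "n_eyes must be an int >= 3"),
            (isinstance(self.seed, int), "seed must be an int"),
            (len(self.icf_modes) >= 1 and set(self.icf_modes) <= {"constant", "individual"},
             "icf_modes must be a non-empty subset of {constant, individual}"),
            (len(self.views) >= 1 and set(self.views) <= {"ODC", "MC"},
             "views must be a non-empty subset of {ODC, MC}"),
            (len(self.scale_factors) >= 1 and all(s > 0 for s in self.scale_factors),
             "scale_factors must be positive"),
            (self.reference_od_um > 0, "reference_od_um must be positive"),
            (self.fov_deg > 0, "fov_deg must be positive"),
            (0 <= self.max_clip_fraction < 1, "max_clip_fraction must be in [0, 1)"),
            (self.laterality_noise_um >= 0, "laterality_noise_um must be >= 0"),
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        self.generation.validate()


def load_config(path) -> ExperimentConfig:
    """Read and validate a YAML experiment configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    gen = raw.pop("generation", {})
    known = set(ExperimentConfig.__dataclass_fields__) - {"generation"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("icf_modes", "views", "scale_factors"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    try:
        gen_params = GenerationParams(**gen)
    except TypeError as exc:
        raise ConfigError(f"invalid generation block: {exc}") from exc
    return ExperimentConfig(generation=gen_params, **raw)


def _eye_seed(base_seed: int, index: int, stream: int = 0) -> int:
    """Deterministic per-eye integer seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(index), int(stream)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _disc_from_meta(vmap: VesselMap) -> OpticDisc:
    return OpticDisc(
        tuple(vmap.meta["od_center"]),
        vmap.meta["od_h_diameter_px"],
        vmap.meta["od_v_diameter_px"],
    )


def _agreement_table(
    per_image: pd.DataFrame,
    key_x: str,
    key_y: str,
    threshold: float,
) -> pd.DataFrame:
    """Bland-Altman + paired-test rows for all twelve characteristics.

    ``per_image`` is long-format with columns (image_id, method, <RVGC>);
    x = method ``key_x``, y = method ``key_y``, d = x - y.
    """
    rows = []
    empty = per_image.empty
    if not empty:
        x_tab = per_image[per_image["method"] == key_x].set_index("image_id")
        y_tab = per_image[per_image["method"] == key_y].set_index("image_id")
        common = x_tab.index.intersection(y_tab.index)
    for name in RVGC_NAMES:
        if empty:
            x = y = np.empty(0)
        else:
            x = x_tab.loc[common, name].to_numpy(dtype=float)
            y = y_tab.loc[common, name].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            rows.append({"rvgc": name, "mean_difference": float("nan"), "sd": float("nan"),
                         "upper_limit": float("nan"), "lower_limit": float("nan"),
                         "bias_p": float("nan"), "prop_bias_p": float("nan"),
                         "paired_p": float("nan"), "test": "none", "n": int(ok.sum()),
                         "significant": False, "degenerate": True})
            continue
        s = PairedSeries(list(common[ok]), x[ok], y[ok])
        ba = bland_altman(s)
        pt = paired_compare(s)
        rows.append({
            "rvgc": name,
            "mean_difference": ba.mean_diff,
            "sd": ba.sd_diff,
            "upper_limit": ba.upper_loa,
            "lower_limit": ba.lower_loa,
            "bias_p": ba.bias_p,
            "prop_bias_p": ba.prop_bias_p,
            "paired_p": pt.p_value,
            "test": pt.test,
            "n": ba.n,
            "significant": bool(np.isfinite(ba.bias_p) and ba.bias_p < threshold),
            "degenerate": ba.degenerate or pt.all_zero,
        })
    return pd.DataFrame(rows)


def _write_outputs(out_dir, tables: Dict[str, pd.DataFrame], log_rows: List[dict]) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")
    with open(out / "flags.jsonl", "w") as fh:
        for row in log_rows:
            fh.write(json.dumps(row, sort_keys=True) + "\n")


def _render_cohort(cfg: ExperimentConfig, view: ViewSpec):
    """Generate and render every eye; returns (eyes, maps, discs)."""
    eyes, maps, discs = [], [], []
    for i in range(cfg.n_eyes):
        eye = generate_eye(cfg.generation, seed=_eye_seed(cfg.seed, i))
        vmap = render_view(eye, view)
        eyes.append(eye)
        maps.append(vmap)
        discs.append(_disc_from_meta(vmap))
    return eyes, maps, discs


def run_icf_comparison(cfg: ExperimentConfig, scale_factor: Optional[float] = None):
    """ODC cohort measured under individual and constant ICF.

    The constant ICF is computed from the rendered disc diameters of the
    whole cohort.  Returns ``(per_image, agreement, log_rows)``; the
    agreement table is shaped like a standard Bland-Altman report with
    d = individual - constant.
    """
    s = scale_factor if scale_factor is not None else cfg.scale_factors[0]
    view = ViewSpec(centering="ODC", scale_factor=s, fov_deg=cfg.fov_deg)
    _, maps, discs = _render_cohort(cfg, view)

    od_list = [mean_od_diameter(d) for d in discs]
    cicf = constant_icf(od_list, cfg.reference_od_um)
    log_rows: List[dict] = []
    if float(np.std(od_list)) == 0:
        log_rows.append({"event": "degenerate_cohort",
                         "detail": "all discs equal; constant ICF == individual ICF"})

    rows = []
    for i, (vmap, disc) in enumerate(zip(maps, discs)):
        iicf = individual_icf(mean_od_diameter(disc), cfg.reference_od_um)
        for method, icf in (("individual", iicf), ("constant", cicf)):
            res = compute_rvgc(vmap, disc, icf)
            rows.append({"image_id": i, "method": method, "icf": icf.value,
                         **res.as_row()})
            log_rows.append({"image_id": i, "method": method, "flags": _clean(res.flags)})
    per_image = pd.DataFrame(rows)
    threshold = bonferroni_threshold(cfg.alpha, len(RVGC_NAMES))
    agreement = _agreement_table(per_image, "individual", "constant", threshold)
    if cfg.out_dir:
        _write_outputs(cfg.out_dir,
                       {"rvgc_per_image_icf": per_image, "agreement_icf": agreement},
                       log_rows)
    return per_image, agreement, log_rows


def run_centering_comparison(cfg: ExperimentConfig):
    """ODC vs. MC views of the same eyes, individual ICF, same vessels.

    Central equivalents in the MC view reuse the vessel selection made
    in the ODC view (matched through stable angular ids).  Images whose
    zone C is clipped beyond ``cfg.max_clip_fraction`` are excluded and
    logged.  Returns ``(per_image, agreement, log_rows)`` with
    d = ODC - MC.
    """
    if not {"ODC", "MC"} <= set(cfg.views):
        raise ConfigError("centering comparison needs both ODC and MC views")
    s = cfg.scale_factors[0]
    rows, log_rows = [], []
    for i in range(cfg.n_eyes):
        eye = generate_eye(cfg.generation, seed=_eye_seed(cfg.seed, i))
        res_by_view = {}
        selection = None
        skip = False
        for centering in ("ODC", "MC"):
            vmap = render_view(eye, ViewSpec(centering=centering, scale_factor=s, fov_deg=cfg.fov_deg))
            disc = _disc_from_meta(vmap)
            iicf = individual_icf(mean_od_diameter(disc), cfg.reference_od_um)
            try:
                res = compute_rvgc(vmap, disc, iicf, selection=selection)
            except MeasurementError as exc:
                log_rows.append({"image_id": i, "view": centering,
                                 "event": "excluded", "detail": str(exc)})
                skip = True
                break
            clip = res.flags.get("zone_c_clip_fraction", 0.0)
            if clip > cfg.max_clip_fraction:
                log_rows.append({"image_id": i, "view": centering, "event": "excluded",
                                 "detail": f"zone C clipped fraction {clip:.3f}"})
                skip = True
                break
            if centering == "ODC":
                selection = res.selection  # reuse the same vessels in the MC view
            res_by_view[centering] = res
            log_rows.append({"image_id": i, "view": centering, "flags": _clean(res.flags)})
        if skip:
            continue
        for centering, res in res_by_view.items():
            rows.append({"image_id": i, "method": centering, "icf": res.icf_used.value,
                         **res.as_row()})
    per_image = pd.DataFrame(rows)
    threshold = bonferroni_threshold(cfg.alpha, len(RVGC_NAMES))
    agreement = _agreement_table(per_image, "ODC", "MC", threshold)
    if cfg.out_dir:
        _write_outputs(cfg.out_dir,
                       {"rvgc_per_image_centering": per_image,
                        "agreement_centering": agreement},
                       log_rows)
    return per_image, agreement, log_rows


def run_laterality_comparison(cfg: ExperimentConfig):
    """Right eye vs. mirrored fellow eye under the cohort constant ICF.

    The fellow eye is the same generative eye with independent caliber
    noise (``cfg.laterality_noise_um``), rendered and mirrored; under
    this null every paired comparison should stay non-significant in
    expectation.  Returns ``(per_image, comparison, log_rows)`` with a
    summary table shaped mean +/- SD per side plus the paired p-value.
    """
    view = ViewSpec(centering="ODC", scale_factor=cfg.scale_factors[0], fov_deg=cfg.fov_deg)
    sides: Dict[str, List] = {"right": [], "left": []}
    discs_all = []
    for i in range(cfg.n_eyes):
        eye = generate_eye(cfg.generation, seed=_eye_seed(cfg.seed, i))
        fellow = perturb_widths(eye, cfg.laterality_noise_um, _eye_seed(cfg.seed, i, stream=1))
        right = render_view(eye, view)
        left = mirror_vessel_map(render_view(fellow, view))
        for side, vmap in (("right", right), ("left", left)):
            disc = _disc_from_meta(vmap)
            sides[side].append((vmap, disc))
            discs_all.append(mean_od_diameter(disc))
    cicf = constant_icf(discs_all, cfg.reference_od_um)

    rows, log_rows = [], []
    for side in ("right", "left"):
        for i, (vmap, disc) in enumerate(sides[side]):
            res = compute_rvgc(vmap, disc, cicf)
            rows.append({"image_id": i, "method": side, "icf": cicf.value, **res.as_row()})
            log_rows.append({"image_id": i, "side": side, "flags": _clean(res.flags)})
    per_image = pd.DataFrame(rows)

    threshold = bonferroni_threshold(cfg.alpha, len(RVGC_NAMES))
    r_tab = per_image[per_image["method"] == "right"].set_index("image_id")
    l_tab = per_image[per_image["method"] == "left"].set_index("image_id")
    rows = []
    for name in RVGC_NAMES:
        x = r_tab[name].to_numpy(dtype=float)
        y = l_tab[name].to_numpy(dtype=float)
        pt = paired_compare(PairedSeries(list(r_tab.index), x, y))
        rows.append({
            "rvgc": name,
            "right_mean": float(np.mean(x)), "right_sd": float(np.std(x, ddof=1)),
            "left_mean": float(np.mean(y)), "left_sd": float(np.std(y, ddof=1)),
            "paired_p": pt.p_value, "test": pt.test,
            "significant": bool(pt.p_value < threshold),
            "all_zero": pt.all_zero,
        })
    comparison = pd.DataFrame(rows)
    if cfg.out_dir:
        _write_outputs(cfg.out_dir,
                       {"rvgc_per_image_laterality": per_image,
                        "comparison_laterality": comparison},
                       log_rows)
    return per_image, comparison, log_rows


def _clean(flags: dict) -> dict:
    """JSON-serializable copy of a flags dict."""
    out = {}
    for k, v in flags.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        out[k] = v
    return out
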