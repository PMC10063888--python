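"""Shared fixtures: one default synthetic eye and one exactly-straight eye,
rendered once per session (rendering and skeleton analysis are the slow
parts of the suite)."""

import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from rvgc import (
    GenerationParams,
    OpticDisc,
    ViewSpec,
    generate_eye,
    individual_icf,
    mean_od_diameter,
    render_view,
)


def disc_of(vmap):
    return OpticDisc(
        vmap.od_center, vmap.meta["od_h_diameter_px"], vmap.meta["od_v_diameter_px"]
    )


def iicf_of(vmap):
    return individual_icf(mean_od_diameter(disc_of(vmap)))


@pytest.fixture(scope="session")
def default_eye():
    return generate_eye(GenerationParams(), seed=1)


@pytest.fixture(scope="session")
def odc_map(default_eye):
    return render_view(default_eye, ViewSpec())


@pytest.fixture(scope="session")
def straight_params():
    # 150 um vessels at 2.5 um/px render exactly 60 px wide; no disc-size
    # spread and no tortuosity, so every geometric quantity is known.
    return GenerationParams(
        true_scale_um_per_px=2.5,
        artery_width_um=(150.0, 0.0),
        vein_width_um=(150.0, 0.0),
        amplitude_frac=(0.0, 0.0),
        od_diameter_um_sd=0.0,
    )


@pytest.fixture(scope="session")
def straight_eye(straight_params):
    return generate_eye(straight_params, seed=7)


@pytest.fixture(scope="session")
def straight_map(straight_eye):
    return render_view(straight_eye, ViewSpec())
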