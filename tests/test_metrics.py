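"""Vessel measurement operations: equivalents, tortuosity, fractal
dimension, and raster-level extraction oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from rvgc import (
    ViewSpec,
    avr,
    build_zones,
    compute_rvgc,
    extract_vessels,
    fractal_dimension_boxcount,
    knudtson_equivalent,
    render_view,
    select_big_six,
    simple_tortuosity,
)
from rvgc.calibration import ConversionFactor
from rvgc.maps_io import VesselMap
from rvgc.metrics import MeasurementError, VesselMeasurement, pad_to_six
from conftest import disc_of, iicf_of


def knudtson_oracle(widths, coef):
    """Brute-force iterative pairing, kept independent of the library."""
    w = np.sort(np.asarray(widths, dtype=float))
    while w.size > 1:
        paired = coef * np.sqrt(w[::-1][: w.size // 2] ** 2 + w[: w.size // 2] ** 2)
        if w.size % 2:
            paired = np.append(paired, w[w.size // 2])
        w = np.sort(paired)
    return float(w[0])


class TestKnudtson:
    def test_equal_width_sextets(self):
        # frozen from the brute-force pairing oracle below
        assert knudtson_equivalent([10] * 6, "artery") == pytest.approx(17.48430, abs=5e-5)
        assert knudtson_equivalent([10] * 6, "vein") == pytest.approx(21.37611, abs=5e-5)

    def test_single_pairing_step(self):
        # one artery pairing of (10, 10): 0.88 * 10 * sqrt(2)
        assert knudtson_oracle([10, 10], 0.88) == pytest.approx(12.44508, abs=5e-5)

    def test_against_oracle_random_sextets(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            w = rng.uniform(5, 60, size=6)
            for vt, c in (("artery", 0.88), ("vein", 0.95)):
                assert knudtson_equivalent(w, vt) == pytest.approx(
                    knudtson_oracle(w, c), rel=1e-12
                )

    @given(st.lists(st.floats(min_value=1, max_value=100), min_size=6, max_size=6),
           st.floats(min_value=0.1, max_value=10), st.randoms())
    @settings(max_examples=40, deadline=None)
    def test_permutation_invariant_and_homogeneous(self, widths, k, rnd):
        shuffled = list(widths)
        rnd.shuffle(shuffled)
        base = knudtson_equivalent(widths, "vein")
        assert knudtson_equivalent(shuffled, "vein") == pytest.approx(base, rel=1e-12)
        assert knudtson_equivalent([k * w for w in widths], "vein") == pytest.approx(
            k * base, rel=1e-9
        )

    def test_errors(self):
        with pytest.raises(MeasurementError):
            knudtson_equivalent([10] * 5, "artery")
        with pytest.raises(MeasurementError):
            knudtson_equivalent([10] * 5 + [-1], "artery")
        with pytest.raises(MeasurementError):
            knudtson_equivalent([10] * 6, "capillary")


def _meas(vid, w, vtype="artery", zone="B"):
    return VesselMeasurement(vid, vtype, zone, w, 1.0, 0.0, 100)


class TestBigSix:
    def test_top_six_descending(self):
        ms = [_meas(i, w) for i, w in enumerate([10, 9, 8, 7, 6, 5, 4, 3])]
        widths, ids, shortfall = select_big_six(ms, "artery")
        assert widths == [10, 9, 8, 7, 6, 5]
        assert not shortfall

    def test_shortfall_flagged_and_padded(self):
        ms = [_meas(i, 5) for i in range(4)]
        widths, ids, shortfall = select_big_six(ms, "artery")
        assert widths == [5, 5, 5, 5] and shortfall
        assert pad_to_six(widths) == [5] * 6

    def test_tie_at_sixth_place_broken_by_id(self):
        ms = [_meas(i, w) for i, w in enumerate([9, 8, 7, 6, 5, 4, 4, 4])]
        _, ids, _ = select_big_six(ms, "artery")
        assert ids == [0, 1, 2, 3, 4, 5]  # first-listed 4 wins on id

    def test_empty_is_error(self):
        with pytest.raises(MeasurementError):
            select_big_six([], "artery")


class TestAvr:
    def test_values(self):
        assert avr(160, 200) == pytest.approx(0.80)
        assert avr(123.4, 123.4) == pytest.approx(1.0)
        assert avr(162, 208) == pytest.approx(0.779, abs=5e-4)

    def test_error(self):
        with pytest.raises(MeasurementError):
            avr(160, 0)


class TestSimpleTortuosity:
    def test_straight_segment(self):
        t = np.linspace(0, 100, 101)
        assert simple_tortuosity(np.column_stack([t, 2 * t])) == pytest.approx(1.0)

    def test_half_circle_at_one_px_sampling(self):
        r = 200.0
        theta = np.linspace(0, np.pi, int(np.pi * r) + 1)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        assert simple_tortuosity(pts) == pytest.approx(np.pi / 2, abs=1e-3)

    def test_sine_period_against_quadrature(self):
        amp, lam = 10.0, 100.0
        arc = quad(lambda x: math.hypot(1.0, 2 * np.pi * amp / lam *
                                        math.cos(2 * np.pi * x / lam)), 0, lam)[0]
        x = np.arange(0, lam + 0.25, 0.25)
        pts = np.column_stack([x, amp * np.sin(2 * np.pi * x / lam)])
        assert simple_tortuosity(pts) == pytest.approx(arc / lam, abs=1e-3)

    def test_errors(self):
        with pytest.raises(MeasurementError):
            simple_tortuosity([[0, 0]])
        with pytest.raises(MeasurementError):
            simple_tortuosity([[0, 0], [1, 1], [0, 0]])


class TestFractalDimension:
    def test_straight_line(self):
        img = np.zeros((512, 512), bool)
        img[256, :] = True
        assert fractal_dimension_boxcount(img) == pytest.approx(1.0, abs=0.05)

    def test_filled_square(self):
        img = np.ones((512, 512), bool)
        assert fractal_dimension_boxcount(img) == pytest.approx(2.0, abs=0.05)

    def test_sierpinski_triangle(self):
        n = 512  # 9 bit-levels >= 6 iterations
        y, x = np.mgrid[0:n, 0:n]
        img = (x & y) == 0
        assert fractal_dimension_boxcount(img) == pytest.approx(
            math.log(3) / math.log(2), abs=0.05
        )

    def test_empty_error(self):
        with pytest.raises(MeasurementError):
            fractal_dimension_boxcount(np.zeros((64, 64), bool))


class TestExtraction:
    def test_rendered_width_oracle(self, straight_map):
        """Straight 150 um vessels at 2.5 um/px must read back 60 +/- 1 px."""
        zones = build_zones(disc_of(straight_map).center, iicf_of(straight_map))
        ms = extract_vessels(straight_map, zones)
        widths = [m.width_px for m in ms if m.zone == "B"]
        assert len(widths) == 14
        assert all(59 <= w <= 61 for w in widths)

    def test_scale_equivariance_of_widths(self, straight_eye, straight_map):
        double = render_view(straight_eye, ViewSpec(scale_factor=2.0))
        z1 = build_zones(disc_of(straight_map).center, iicf_of(straight_map))
        z2 = build_zones(disc_of(double).center, iicf_of(double))
        w1 = np.mean([m.width_px for m in extract_vessels(straight_map, z1) if m.zone == "B"])
        w2 = np.mean([m.width_px for m in extract_vessels(double, z2) if m.zone == "B"])
        assert w2 / w1 == pytest.approx(2.0, rel=0.03)

    def test_zero_artery_map_yields_empty_list_and_warning(self, straight_map):
        labels = straight_map.labels.copy()
        labels[labels == 1] = 0
        vmap = VesselMap(labels, dict(straight_map.meta))
        zones = build_zones(disc_of(vmap).center, iicf_of(vmap))
        ms, flags = extract_vessels(vmap, zones, with_flags=True)
        assert [m for m in ms if m.vessel_type == "artery"] == []
        assert any("artery" in w for w in flags["warnings"])

    def test_zone_b_outside_image_is_an_error(self, straight_map):
        # a tiny ICF blows the annuli far beyond the frame
        icf = ConversionFactor(0.3, "individual")
        zones = build_zones(disc_of(straight_map).center, icf)
        with pytest.raises(MeasurementError):
            extract_vessels(straight_map, zones)


class TestComputeRvgc:
    def test_straight_eye_unit_tortuosity_and_symmetric_avr(self, straight_map):
        res = compute_rvgc(straight_map, disc_of(straight_map), iicf_of(straight_map))
        assert res.STt == pytest.approx(1.0, abs=1e-3)
        assert res.STa == pytest.approx(1.0, abs=1e-3)
        assert res.STv == pytest.approx(1.0, abs=1e-3)
        # equal artery and vein calibers: AVR reduces to the ratio of the
        # equal-width pairing factors of the two coefficient sets
        expected = knudtson_oracle([1] * 6, 0.88) / knudtson_oracle([1] * 6, 0.95)
        assert res.AVR == pytest.approx(expected, rel=0.02)
        assert res.CRAE / res.CRVE == pytest.approx(res.AVR)
        assert 0 < res.Df <= 2

    def test_dimensionless_rvgc_do_not_depend_on_icf_kind(self, straight_map):
        """AVR, ST and Df are pixel-ratio quantities: measuring the same
        image with a different (here: equal-valued constant) ICF changes
        the um equivalents only."""
        disc = disc_of(straight_map)
        iicf = iicf_of(straight_map)
        cicf = ConversionFactor(iicf.value, "constant")
        a = compute_rvgc(straight_map, disc, iicf)
        b = compute_rvgc(straight_map, disc, cicf)
        for name in ("AVR", "STt", "Df", "Dfa", "Dfv"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-9)

    def test_larger_icf_zone_measures_wider_tapering_vessels(self, straight_params):
        """A larger ICF shrinks the annulus toward the disc, where
        tapering vessels are wider."""
        import dataclasses

        from rvgc import generate_eye

        params = dataclasses.replace(straight_params, taper_per_od=0.15)
        vmap = render_view(generate_eye(params, seed=3), ViewSpec())
        disc = disc_of(vmap)
        base = iicf_of(vmap).value
        means = []
        for icf_val in (base * 0.9, base * 1.15):
            zones = build_zones(disc.center, ConversionFactor(icf_val, "individual"))
            ms = extract_vessels(vmap, zones)
            means.append(np.mean([m.width_px for m in ms if m.zone == "C"]))
        assert means[1] >= means[0] - 1e-6
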