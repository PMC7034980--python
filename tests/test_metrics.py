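"""Primary and secondary junction parameters against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from junctmorph import (
    BinaryMask,
    RasterImage,
    covered_runs,
    derive_secondary,
    dilate_interface,
    measure_primary,
    measure_second_marker,
    path_length,
)
from junctmorph.metrics import PrimaryMeasures
from junctmorph.topology import InterfaceRecord

from conftest import straight_junction
from oracles import brute_band, brute_path_length, brute_primary

SQRT2 = math.sqrt(2.0)


def random_walk_path(rng, shape, n_steps):
    h, w = shape
    r, c = int(rng.integers(5, h - 5)), int(rng.integers(5, w - 5))
    path = [(r, c)]
    moves = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
             (0, 1), (1, -1), (1, 0), (1, 1)]
    for _ in range(n_steps):
        for _ in range(20):
            dr, dc = moves[int(rng.integers(0, 8))]
            rr, cc = path[-1][0] + dr, path[-1][1] + dc
            if 1 <= rr < h - 1 and 1 <= cc < w - 1 and (rr, cc) != path[-1]:
                path.append((rr, cc))
                break
    return tuple(path)


class TestPathLength:
    def test_collinear_and_diagonal(self):
        assert path_length([(0, c) for c in range(11)]) == pytest.approx(10.0)
        stairs = [(i, i) for i in range(6)]
        assert path_length(stairs) == pytest.approx(5 * SQRT2)

    def test_l_path_and_linearity(self):
        path = [(0, c) for c in range(31)] + [(r, 30) for r in range(1, 41)]
        length = path_length(path)
        assert length == pytest.approx(70.0)
        euclid = math.dist(path[0], path[-1])
        assert euclid == pytest.approx(50.0)
        assert length / euclid == pytest.approx(1.4)

    def test_non_adjacent_pixels_rejected(self):
        with pytest.raises(ValueError):
            path_length([(0, 0), (0, 2)])
        with pytest.raises(ValueError):
            path_length([(0, 0), (0, 0), (0, 1)])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 60))
    def test_matches_oracle_and_bounds_euclid(self, seed, n):
        rng = np.random.default_rng(seed)
        path = random_walk_path(rng, (80, 80), n)
        got = path_length(path)
        assert got == pytest.approx(brute_path_length(path), abs=1e-9)
        assert got >= math.dist(path[0], path[-1]) - 1e-9


class TestDilateInterface:
    def test_straight_path_area_closed_form(self):
        path = tuple((50, c) for c in range(10, 111))  # 101 pixels
        rec = InterfaceRecord(1, 1, 2, path, (1, 2))
        band = dilate_interface(rec, 2, (200, 200))
        assert band.area == (101 + 4) * 5  # 525

    def test_single_pixel_block(self):
        rec = InterfaceRecord(1, 1, 2, ((10, 10), (10, 11)), (1, 2))
        band = dilate_interface(rec, 1, (30, 30))
        assert band.area == 12  # 3x4 block around a 2-px path

    def test_band_nesting_and_range_check(self):
        rng = np.random.default_rng(3)
        path = random_walk_path(rng, (64, 64), 25)
        rec = InterfaceRecord(1, 1, 2, path, (1, 2))
        b1 = dilate_interface(rec, 1, (64, 64)).pixels
        b2 = dilate_interface(rec, 2, (64, 64)).pixels
        assert not (b1 & ~b2).any()
        with pytest.raises(ValueError):
            dilate_interface(rec, 0, (64, 64))
        with pytest.raises(ValueError):
            dilate_interface(rec, 10, (64, 64))

    def test_matches_brute_enumeration(self):
        rng = np.random.default_rng(11)
        path = random_walk_path(rng, (48, 48), 20)
        rec = InterfaceRecord(1, 1, 2, path, (1, 2))
        band = dilate_interface(rec, 3, (48, 48))
        got = set(map(tuple, np.argwhere(band.pixels)))
        assert got == brute_band(path, 3, (48, 48))


class TestCoveredRuns:
    def test_programmed_runs_recovered(self):
        rec, img = straight_junction(runs=((10, 39), (60, 79)))
        band = dilate_interface(rec, 2, img.shape)
        marker = BinaryMask(img.pixels > 100)
        assert covered_runs(rec, band, marker) == [(10, 39), (60, 79)]

    def test_full_and_empty_marker(self):
        rec, img = straight_junction(runs=((0, 100),))
        band = dilate_interface(rec, 2, img.shape)
        assert covered_runs(rec, band, BinaryMask(img.pixels > 100)) == [
            (0, 100)
        ]
        empty = BinaryMask(np.zeros(img.shape, bool))
        assert covered_runs(rec, band, empty) == []


class TestMeasurePrimary:
    def test_two_run_index_arithmetic(self):
        rec, img = straight_junction(runs=((10, 39), (60, 79)))
        band = dilate_interface(rec, 2, img.shape)
        p = measure_primary(rec, band, img, 100)
        assert p.fragmented_junction_contour == pytest.approx(29 + 19)
        assert p.junction_contour == pytest.approx(69)
        assert p.straight_junction_length == pytest.approx(69)
        assert p.interface_contour == pytest.approx(100)

    def test_full_coverage_degenerate_equalities(self):
        rec, img = straight_junction(runs=((0, 100),))
        band = dilate_interface(rec, 2, img.shape)
        p = measure_primary(rec, band, img, 100)
        assert p.junction_contour == p.interface_contour
        assert p.fragmented_junction_contour == p.interface_contour
        assert p.straight_junction_length == p.straight_interface_length
        marker = img.pixels > 100
        assert p.marker_area == int((marker & band.pixels).sum())

    def test_empty_marker_zeroes_junction_fields(self):
        rec, img = straight_junction(runs=())
        band = dilate_interface(rec, 2, img.shape)
        p = measure_primary(rec, band, img, 100)
        assert p.junction_contour == 0
        assert p.marker_area == 0
        assert p.interface_contour == pytest.approx(100)

    def test_primary_invariants_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            path = random_walk_path(rng, (64, 64), int(rng.integers(8, 40)))
            rec = InterfaceRecord(1, 1, 2, path, (1, 2))
            img = RasterImage(
                rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
            )
            d = int(rng.integers(1, 4))
            band = dilate_interface(rec, d, (64, 64))
            p = measure_primary(rec, band, img, float(rng.integers(0, 250)))
            assert (
                p.fragmented_junction_contour
                <= p.junction_contour + 1e-9
                <= p.interface_contour + 2e-9
            )
            assert p.straight_interface_length <= p.interface_contour + 1e-9
            assert p.straight_junction_length <= p.junction_contour + 1e-9
            assert p.marker_area <= p.interface_area
            assert p.junction_area <= p.interface_area

    def test_equals_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            path = random_walk_path(rng, (48, 48), int(rng.integers(8, 30)))
            rec = InterfaceRecord(1, 1, 2, path, (1, 2))
            img = rng.integers(0, 256, size=(48, 48)).astype(np.uint8)
            t = float(rng.integers(0, 250))
            d = int(rng.integers(1, 4))
            band = dilate_interface(rec, d, (48, 48))
            p = measure_primary(rec, band, RasterImage(img), t)
            ref = brute_primary(path, d, (48, 48), img, t)
            assert p.interface_area == ref["interface_area"]
            assert p.marker_area == ref["marker_area"]
            assert p.junction_area == ref["junction_area"]
            assert p.marker_intensity == pytest.approx(
                ref["marker_intensity"], abs=1e-9
            )
            for name in (
                "interface_contour",
                "fragmented_junction_contour",
                "junction_contour",
                "straight_interface_length",
                "straight_junction_length",
            ):
                assert getattr(p, name) == pytest.approx(
                    ref[name], abs=1e-9
                ), name


class TestDeriveSecondary:
    def test_straight_uniform_fully_covered(self):
        rec, img = straight_junction(runs=((0, 100),), intensity=200)
        band = dilate_interface(rec, 2, img.shape)
        p = measure_primary(rec, band, img, 100)
        s = derive_secondary(p)
        assert s.interface_linearity_index == pytest.approx(1.0)
        assert s.coverage_index == pytest.approx(100.0)
        assert s.cluster_density == pytest.approx(200.0)

    def test_ratio_arithmetic(self):
        p = PrimaryMeasures(
            interface_contour=100.0,
            straight_interface_length=100.0,
            interface_area=400,
            junction_contour=80.0,
            straight_junction_length=80.0,
            junction_area=320,
            fragmented_junction_contour=50.0,
            marker_area=100,
            marker_intensity=1000.0,
        )
        s = derive_secondary(p)
        assert s.coverage_index == pytest.approx(50.0)
        assert s.interface_occupancy == pytest.approx(25.0)
        assert s.intensity_per_interface_area == pytest.approx(2.5)
        assert s.cluster_density == pytest.approx(10.0)
        alt = derive_secondary(p, "junction_area")
        assert alt.cluster_density == pytest.approx(1000.0 / 320)

    def test_zero_marker_reports_missing_not_error(self):
        p = PrimaryMeasures(100.0, 100.0, 400, 0.0, 0.0, 0, 0.0, 0, 0.0)
        s = derive_secondary(p)
        assert math.isnan(s.junction_linearity_index)
        assert math.isnan(s.cluster_density)
        assert s.coverage_index == 0.0

    def test_degenerate_interface_errors(self):
        p = PrimaryMeasures(0.0, 0.0, 0, 0.0, 0.0, 0, 0.0, 0, 0.0)
        with pytest.raises(ValueError):
            derive_secondary(p)


class TestSecondMarker:
    def test_identical_marker_identical_measures(self):
        rec, img = straight_junction(runs=((10, 39),))
        band = dilate_interface(rec, 2, img.shape)
        p1 = measure_primary(rec, band, img, 100)
        p2, _ = measure_second_marker(rec, band, img, 100)
        assert p1 == p2

    def test_empty_second_marker_keeps_interface_geometry(self):
        rec, img = straight_junction(runs=((10, 39),))
        band = dilate_interface(rec, 2, img.shape)
        blank = RasterImage(np.zeros(img.shape, dtype=np.uint8))
        p2, _ = measure_second_marker(rec, band, blank, 100)
        assert p2.marker_area == 0
        assert p2.interface_contour == pytest.approx(100.0)
        assert p2.interface_area == dilate_interface(rec, 2, img.shape).area

    def test_doubled_intensity_doubles_intensity_only(self):
        rec, img = straight_junction(runs=((10, 39),), intensity=100)
        band = dilate_interface(rec, 2, img.shape)
        doubled = RasterImage(
            np.where(img.pixels > 50, img.pixels * 2, img.pixels).astype(
                np.uint8
            )
        )
        pa, _ = measure_second_marker(rec, band, img, 50)
        pb, _ = measure_second_marker(rec, band, doubled, 50)
        assert pb.marker_area == pa.marker_area
        assert pb.fragmented_junction_contour == pa.fragmented_junction_contour
        assert pb.marker_intensity == pytest.approx(2 * pa.marker_intensity)


class TestSettingInvariants:
    def test_dilation_ladder_on_isolated_junction(self):
        rec, img = straight_junction(
            runs=((10, 39), (60, 79)), stain_width=5
        )
        prev = None
        for d in range(1, 6):
            band = dilate_interface(rec, d, img.shape)
            p = measure_primary(rec, band, img, 100)
            if prev is not None:
                assert p.interface_contour == prev.interface_contour
                assert (
                    p.fragmented_junction_contour
                    == prev.fragmented_junction_contour
                )
                assert p.marker_area >= prev.marker_area
                assert p.marker_intensity >= prev.marker_intensity
            prev = p

    def test_threshold_ladder_on_noisy_junction(self):
        rec, img = straight_junction(runs=((5, 50), (70, 95)))
        rng = np.random.default_rng(2)
        noisy = RasterImage(
            np.clip(
                img.as_float() + rng.normal(0, 10, img.shape), 0, 255
            ),
            8,
        )
        band = dilate_interface(rec, 2, img.shape)
        prev = None
        for t in (60, 90, 120, 150, 180, 250):
            p = measure_primary(rec, band, noisy, t)
            if prev is not None:
                assert p.interface_contour == prev.interface_contour
                assert p.marker_area <= prev.marker_area
                assert p.marker_intensity <= prev.marker_intensity + 1e-9
                assert (
                    p.fragmented_junction_contour
                    <= prev.fragmented_junction_contour + 1e-9
                )
            prev = p
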