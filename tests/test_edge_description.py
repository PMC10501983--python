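import numpy as np
import pytest

from conftest import brute_force_accumulator, brute_force_peaks
from periomark.config import PipelineConfig
from periomark.edge_description import (
    EdgeGroup, EdgeMap, HoughLine,
    extract_segments, filter_by_slope, fit_edge, group_and_label,
    hough_accumulate, hough_to_slope_intercept, select_degree,
    _accumulator, _peaks,
)
from periomark.errors import DescriptionError, FitError


def edge_map(shape, coords):
    data = np.zeros(shape, dtype=bool)
    for x, y in coords:
        data[y, x] = True
    return EdgeMap(data)


class TestHoughAccumulate:
    def test_vertical_line_peak(self):
        e = edge_map((120, 120), [(50, y) for y in range(10, 110)])
        lines = hough_accumulate(e)
        top = lines[0]
        assert (top.theta, top.rho, top.votes) == (0.0, 50.0, 100)

    def test_two_orthogonal_lines(self):
        coords = [(30, y) for y in range(60)] + [(x, 20) for x in range(60)]
        lines = hough_accumulate(edge_map((64, 64), coords))
        found = {(l.rho, l.theta) for l in lines[:2]}
        assert (30.0, 0.0) in found    # vertical x = 30
        assert (20.0, 90.0) in found   # horizontal y = 20

    def test_single_pixel_yields_no_peaks(self):
        lines = hough_accumulate(edge_map((32, 32), [(5, 5)]), min_votes=15)
        assert lines == []

    def test_empty_map_raises(self):
        with pytest.raises(DescriptionError):
            hough_accumulate(EdgeMap(np.zeros((16, 16), dtype=bool)))

    def test_matches_brute_force_bin_for_bin(self):
        rng = np.random.default_rng(8)
        for _ in range(6):
            h, w = rng.integers(24, 49, size=2)
            data = np.zeros((h, w), dtype=bool)
            # a random line plus sprinkled noise pixels
            x0, slope = rng.uniform(5, w - 5), rng.uniform(-0.5, 0.5)
            for y in range(h):
                x = int(round(x0 + slope * y))
                if 0 <= x < w:
                    data[y, x] = True
            noise = rng.random((h, w)) < 0.02
            data |= noise
            ys, xs = np.nonzero(data)
            acc, off = _accumulator(xs, ys, data.shape)
            b_acc, b_off = brute_force_accumulator(data)
            assert off == b_off
            np.testing.assert_array_equal(acc, b_acc)
            got = [(l.rho, l.theta, l.votes)
                   for l in _peaks(acc, off, 16, 5)]
            assert got == brute_force_peaks(b_acc, b_off, 16, 5)


class TestSlopeIntercept:
    def test_horizontal_line(self):
        m, d = hough_to_slope_intercept(HoughLine(rho=5, theta=90, votes=1))
        assert (m, d) == pytest.approx((0.0, 5.0))

    def test_diagonal_satisfies_both_relations(self):
        h = HoughLine(rho=np.sqrt(2), theta=45, votes=1)
        m, d = hough_to_slope_intercept(h)
        assert m == pytest.approx(-1.0)
        assert d == pytest.approx(2.0)
        # points on y = m x + d satisfy rho = x cos + y sin
        theta = np.deg2rad(45)
        for x in (-3.0, 0.0, 7.5):
            y = m * x + d
            assert x * np.cos(theta) + y * np.sin(theta) == pytest.approx(
                np.sqrt(2), abs=1e-12)

    def test_vertical_line_signals(self):
        with pytest.raises(FitError):
            hough_to_slope_intercept(HoughLine(rho=10, theta=0, votes=1))

    def test_roundtrip_residual_below_1e9(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            theta_deg = rng.uniform(5, 175)
            rho = rng.uniform(-100, 100)
            m, d = hough_to_slope_intercept(
                HoughLine(rho=rho, theta=theta_deg, votes=1))
            theta = np.deg2rad(theta_deg)
            xs = rng.uniform(-50, 50, size=20)
            ys = m * xs + d
            resid = np.abs(xs * np.cos(theta) + ys * np.sin(theta) - rho)
            assert resid.max() < 1e-9


class TestFilterBySlope:
    @pytest.mark.parametrize("theta, kept", [
        (135, True),    # line at 45 deg from horizontal
        (116.57, False),  # slope 0.5 -> 26.57 deg
        (0, True),      # vertical line, 90 deg
        (90, False),    # horizontal line
        (60, True),     # line at 30 deg: boundary is inclusive
    ])
    def test_min_angle(self, theta, kept):
        lines = filter_by_slope([HoughLine(rho=0, theta=theta, votes=50)], 30)
        assert bool(lines) is kept


class TestExtractSegments:
    def test_ideal_vertical_edge_fully_retained(self):
        e = edge_map((100, 100), [(40, y) for y in range(10, 90)])
        line = HoughLine(rho=40, theta=0, votes=80)
        out = extract_segments(e, [line])
        assert out.count == 80

    def test_far_pixels_removed(self):
        coords = [(40, y) for y in range(10, 90)] + [(60, 50)]
        e = edge_map((100, 100), coords)
        out = extract_segments(e, [HoughLine(rho=40, theta=0, votes=80)])
        assert not out.data[50, 60]

    def test_curved_edge_covered_by_piecewise_lines(self):
        # parabola x = 30 + 0.001*y^2 over 200 rows, described by its
        # own Hough peaks
        ys = np.arange(200)
        xs = np.round(30 + 0.02 * ys + 0.0008 * ys ** 2).astype(int)
        e = edge_map((220, 120), list(zip(xs, ys)))
        lines = filter_by_slope(hough_accumulate(e, n_peaks=8, min_votes=10))
        out = extract_segments(e, lines)
        assert out.count >= 0.95 * len(ys)


class TestGroupAndLabel:
    def test_parallel_chains_stay_separate(self):
        coords = [(30, y) for y in range(20, 80)] + [
            (50, y) for y in range(20, 80)]
        e = edge_map((100, 100), coords)
        groups = group_and_label(e, e)
        assert len(groups) == 2

    def test_collinear_chains_with_small_offset_merge(self):
        coords = [(30, y) for y in range(10, 50)] + [
            (33, y) for y in range(50, 90)]
        e = edge_map((100, 100), coords)
        groups = group_and_label(e, e)
        assert len(groups) == 1
        assert groups[0].size == 80

    def test_small_blob_dropped(self):
        chain = [(30, y) for y in range(10, 80)]
        blob = [(70, 40), (70, 41)]
        e = edge_map((100, 100), chain + blob)
        groups = group_and_label(e, e)
        assert len(groups) == 1
        assert 70 not in groups[0].xs


class TestFits:
    def _group(self, ys, xs):
        return EdgeGroup(label=1, xs=np.asarray(xs, float),
                         ys=np.asarray(ys, float))

    def test_exact_line_recovery(self):
        ys = np.arange(50, dtype=float)
        g = self._group(ys, 10 + 0.1 * ys)
        fit = fit_edge(g, 1)
        assert fit.coeffs == pytest.approx((10.0, 0.1), abs=1e-9)
        assert fit.mse == pytest.approx(0.0, abs=1e-12)

    def test_exact_parabola_recovery(self):
        ys = np.arange(100, dtype=float)
        g = self._group(ys, 5 + 0.2 * ys + 0.001 * ys ** 2)
        fit = fit_edge(g, 2)
        assert fit.coeffs == pytest.approx((5.0, 0.2, 0.001), abs=1e-6)
        assert fit.mse == pytest.approx(0.0, abs=1e-9)
        assert fit_edge(g, 1).mse > 0.1

    def test_rank_deficient_raises(self):
        g = self._group([7.0] * 10, np.arange(10, dtype=float))
        with pytest.raises(FitError):
            fit_edge(g, 1)

    def test_select_degree_prefers_low_on_ties(self):
        ys = np.arange(40, dtype=float)
        assert select_degree(self._group(ys, 3 + 0.5 * ys)).degree == 1

    def test_select_degree_finds_curvature(self):
        ys = np.arange(120, dtype=float)
        g = self._group(ys, 10 + 0.1 * ys + 0.002 * ys ** 2)
        assert select_degree(g).degree == 2

    def test_select_degree_robust_to_noise(self):
        wins = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            ys = np.arange(200, dtype=float)
            xs = 10 + 0.1 * ys + 0.001 * ys ** 2 + rng.normal(0, 0.5, 200)
            if select_degree(self._group(ys, xs)).degree == 2:
                wins += 1
        assert wins >= 27
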