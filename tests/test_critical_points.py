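import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import truth_lookup
from periomark import critical_points as cp
from periomark.config import PipelineConfig
from periomark.edge_description import EdgeGroup, FittedEdge, PolynomialFit
from periomark.pipeline import analyze
from periomark.radiograph_io import BoundingBox, Radiograph
from periomark.synthetic import PhantomSpec, emit_detections, render_phantom


def make_scan(left, right, y0=200.0, direction=-1):
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    n = len(left)
    ys = y0 + direction * np.arange(n, dtype=float)
    return cp.ProfileScan(ys=ys, xs=np.full(n, 50.0), left=left, right=right)


def straight_edge(x0=50.0):
    n = 30
    ys = np.arange(100, 100 + n, dtype=float)
    g = EdgeGroup(label=1, xs=np.full(n, x0), ys=ys)
    line = PolynomialFit(1, (x0, 0.0), 0.0)
    curve = PolynomialFit(2, (x0, 0.0, 0.0), 0.0)
    return FittedEdge(group=g, line=line, curve=curve, side="left")


class TestCumRule:
    def test_worked_example(self):
        scan = make_scan([10, 20], [15, 5])
        assert scan.cum.tolist() == [10.0, 5.0]

    def test_tie_takes_else_branch(self):
        scan = make_scan([30, 30], [30, 30])
        np.testing.assert_array_equal(scan.cum, scan.right)

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 255, allow_nan=False),
                st.floats(0, 255, allow_nan=False),
            ),
            min_size=2, max_size=40,
        )
    )
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_cum_equals_elementwise_min(self, pairs):
        left = np.array([p[0] for p in pairs])
        right = np.array([p[1] for p in pairs])
        scan = make_scan(left, right)
        np.testing.assert_array_equal(scan.cum, np.minimum(left, right))


class TestFirstCriticalPoint:
    def test_step_profile_detected_at_drop(self, config):
        scan = make_scan([120.0] * 10 + [60.0] * 10, [200.0] * 20)
        edge = straight_edge()
        x_f, y_f, p = cp.first_critical_point(scan, edge, config)
        assert p == 10
        assert y_f == scan.ys[10]
        assert x_f == 50.0

    def test_flat_profile_yields_none(self, config):
        scan = make_scan([120.0] * 30, [200.0] * 30)
        assert cp.first_critical_point(scan, straight_edge(), config) is None

    def test_single_dip_ignored_by_persistence(self, config):
        vals = [120.0, 60.0] + [120.0] * 18
        scan = make_scan(vals, [200.0] * 20)
        assert cp.first_critical_point(scan, straight_edge(), config) is None

    def test_shallow_drop_below_mean_is_not_abrupt(self, config):
        # stays under the mean for a while but never 20 levels below
        vals = [125.0] * 15 + [115.0] * 15
        scan = make_scan(vals, [200.0] * 30)
        assert cp.first_critical_point(scan, straight_edge(), config) is None


class TestReferenceLevel:
    def test_mean_of_five_samples_past_p(self):
        left = [120.0] * 10 + [60.0] * 10
        right = [200.0] * 10 + [60.0, 62.0, 58.0, 60.0, 60.0] + [200.0] * 5
        scan = make_scan(left, right)  # min side is L -> opposite is R
        assert scan.phase1_side(9) == "L"
        assert cp.reference_level(scan, 9) == pytest.approx(60.0)

    def test_constant_tail(self):
        scan = make_scan([10.0] * 12, [50.0] * 12)
        assert cp.reference_level(scan, 3) == pytest.approx(50.0)

    def test_too_few_remaining_samples(self):
        scan = make_scan([10.0] * 10, [50.0] * 10)
        assert cp.reference_level(scan, 5) is None


class TestSecondCriticalPoint:
    def _scan_with_bright_run(self, tail):
        left = [120.0] * 5 + [60.0] * (len(tail))
        right = [200.0] * 5 + list(tail)
        return make_scan(left, right)

    def test_run_detected_at_first_bright_sample(self, config):
        tail = [65.0, 70.0, 200.0, 210.0, 220.0, 230.0, 240.0]
        scan = self._scan_with_bright_run(tail)
        edge = straight_edge()
        x_s, y_s, idx = cp.second_critical_point(scan, edge, 4, 70.0, config)
        assert idx == 4 + 1 + 2
        assert y_s == scan.ys[idx]

    def test_no_run_returns_none(self, config):
        scan = self._scan_with_bright_run([65.0] * 10)
        assert cp.second_critical_point(scan, straight_edge(), 4, 70.0,
                                        config) is None

    def test_short_tail_run_returns_none(self, config):
        tail = [65.0] * 4 + [240.0] * 4  # only 4 bright samples remain
        scan = self._scan_with_bright_run(tail)
        assert cp.second_critical_point(scan, straight_edge(), 4, 70.0,
                                        config) is None


class TestOnPhantom:
    def test_detected_pair_close_to_truth(self, analyzed):
        r, truth, dset, report, art = analyzed
        tmap = truth_lookup(truth)
        checked = 0
        for edge, pair in zip(art.edges, art.pairs):
            t = tmap.get((edge.implant_id, edge.side))
            if t is None or not t.critical or pair.status != "both":
                continue
            for det, tru in zip((pair.first, pair.second), t.critical):
                assert np.hypot(det[0] - tru[0], det[1] - tru[1]) <= 3.0
            checked += 1
        assert checked >= 3

    def test_traversal_ordering(self, analyzed):
        *_, art = analyzed
        for pair in art.pairs:
            if pair.status == "both":
                assert pair.first_index < pair.second_index

    def test_zero_defect_gives_status_none(self):
        imps = tuple(
            dataclasses.replace(g, defect_fraction=0.0)
            for g in PhantomSpec().implants
        )
        r, truth = render_phantom(PhantomSpec(implants=imps, seed=3))
        dset = emit_detections(truth, jitter=0.0, seed=4)
        report, art = analyze(r, dset)
        statuses = [p.status for p in art.pairs]
        assert statuses.count("none") >= len(statuses) - 1
        assert report.no_resorption_detected or len(
            report.measured_percentages) <= 1

    def test_crown_verification_downgrades_displaced_boxes(self, phantom,
                                                           config):
        r, truth = phantom
        dset = emit_detections(truth, jitter=0.0, seed=5)
        _, art = analyze(r, dset)
        edge = next(e for e, p in zip(art.edges, art.pairs)
                    if p.status == "both")
        cfg = config.replace(verify_crown=True)
        far_crown = [BoundingBox("crown", x=1, y=1, w=5, h=5, score=0.9)]
        pair = cp.detect_edge_critical_pair(r, edge, "lower", far_crown, cfg)
        assert pair.status == "first_only"

    def test_vertical_flip_mirrors_critical_points(self):
        spec = PhantomSpec(seed=6)
        r_lo, t_lo = render_phantom(spec)
        r_up, t_up = render_phantom(dataclasses.replace(spec, jaw="upper"))
        rep_lo, _ = analyze(r_lo, emit_detections(t_lo, 0.0, seed=7))
        rep_up, _ = analyze(r_up, emit_detections(t_up, 0.0, seed=7))
        lo = {(e.implant_id, e.side): e for e in rep_lo.edges
              if e.first is not None}
        up = {(e.implant_id, e.side): e for e in rep_up.edges
              if e.first is not None}
        shared = set(lo) & set(up)
        assert len(shared) >= 3
        H = r_lo.height - 1
        for key in shared:
            assert abs((H - lo[key].first[1]) - up[key].first[1]) <= 1.0
            if lo[key].second and up[key].second:
                assert abs((H - lo[key].second[1]) - up[key].second[1]) <= 1.0
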