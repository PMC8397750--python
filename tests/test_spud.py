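"""Ring-curve fitting and unsupervised circular time decoding."""

import numpy as np
import pytest

from ringdrift import spud
from ringdrift._utils import circular_diff
from ringdrift.spud import Alignment, RingCurve


def ring_points(n=500, r=1.0, noise=0.0, seed=0, d=2):
    rng = np.random.default_rng(seed)
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    pts = r * np.c_[np.cos(theta), np.sin(theta)]
    if d > 2:
        pts = np.c_[pts, np.zeros((n, d - 2))]
    if noise:
        pts = pts + noise * rng.normal(size=pts.shape)
    return pts, theta


class TestSplit:
    def test_sizes_disjoint_exhaustive_deterministic(self):
        train, test = spud.split_train_test(100, 0.8, seed=1)
        assert train.size == 80 and test.size == 20
        assert np.intersect1d(train, test).size == 0
        np.testing.assert_array_equal(
            np.sort(np.r_[train, test]), np.arange(100))
        train2, _ = spud.split_train_test(100, 0.8, seed=1)
        np.testing.assert_array_equal(train, train2)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            spud.split_train_test(100, 1.0)


class TestKnots:
    def test_planted_cluster_centers_recovered(self):
        rng = np.random.default_rng(2)
        centers = ring_points(10, r=5.0, seed=3)[0]
        pts = np.vstack([c + 0.05 * rng.normal(size=(50, 2)) for c in centers])
        knots = spud.init_knots(pts, n_knots=10, seed=0)
        # every true center has a knot within the cluster noise scale
        for c in centers:
            assert np.linalg.norm(knots - c, axis=1).min() < 0.15

    def test_single_knot_is_centroid(self):
        rng = np.random.default_rng(4)
        pts = rng.random((200, 2))
        knot = spud.init_knots(pts, n_knots=1, seed=0)
        np.testing.assert_allclose(knot[0], pts.mean(axis=0), atol=1e-9)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        pts = rng.random((100, 2))
        a = spud.init_knots(pts, 5, seed=2)
        b = spud.init_knots(pts, 5, seed=2)
        np.testing.assert_array_equal(a, b)

    def test_fewer_points_than_knots_rejected(self):
        with pytest.raises(ValueError):
            spud.init_knots(np.zeros((3, 2)), n_knots=5)


class TestConnect:
    def test_circular_order_recovered_on_dense_ring(self):
        pts, _ = ring_points(1500, r=2.0, noise=0.03, seed=6)
        angles = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        knots = 2.0 * np.c_[np.cos(angles), np.sin(angles)]
        perm = np.random.default_rng(7).permutation(10)
        ring = spud.connect_knots(pts, knots[perm])
        # successive knots on the fitted ring must be circular neighbors
        order = [int(np.argmin(np.linalg.norm(knots - k, axis=1)))
                 for k in ring.knots]
        diffs = np.diff(order + [order[0]]) % 10
        assert set(diffs) == {1} or set(diffs) == {9}

    def test_three_knots_always_triangle(self):
        pts = np.random.default_rng(8).random((50, 2))
        knots = np.array([[0.0, 0], [1, 0], [0, 1]])
        ring = spud.connect_knots(pts, knots)
        assert ring.n_knots == 3

    def test_empty_tubes_fall_back_to_angular_order(self, caplog):
        # points far away from every knot segment
        pts = np.array([[100.0, 100.0]] * 5)
        angles = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        knots = np.c_[np.cos(angles), np.sin(angles)]
        with caplog.at_level("WARNING"):
            ring = spud.connect_knots(pts, knots)
        assert ring.n_knots == 6
        assert "fallback" in caplog.text


class TestOptimize:
    def test_points_on_ring_are_near_stationary(self):
        angles = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        knots = np.c_[np.cos(angles), np.sin(angles)]
        pts = RingCurve(knots=knots).knots[
            np.repeat(np.arange(10), 20)
        ]  # points exactly at the knots
        before = spud.curve_objective(pts, RingCurve(knots=knots))
        curve = spud.optimize_knots(pts, RingCurve(knots=knots), n_iter=10)
        after = spud.curve_objective(pts, curve)
        assert after <= before

    def test_noisy_circle_improves_from_poor_init(self):
        pts, _ = ring_points(500, r=3.0, noise=0.1, seed=9)
        rng = np.random.default_rng(10)
        init = RingCurve(knots=pts[rng.choice(len(pts), 8, replace=False)])
        a0 = np.abs(spud.project_to_curve(pts, init).offset).mean()
        curve = spud.optimize_knots(pts, init, n_iter=60)
        a1 = np.abs(spud.project_to_curve(pts, curve).offset).mean()
        assert a1 < a0

    def test_objective_matches_brute_force_nearest_segment(self):
        rng = np.random.default_rng(11)
        knots = rng.random((6, 2)) * 10
        curve = RingCurve(knots=knots)
        pts = rng.random((40, 2)) * 10
        manual = 0.0
        for x in pts:
            best = np.inf
            for j in range(6):
                a = knots[j]
                b = knots[(j + 1) % 6]
                v = b - a
                t = np.clip((x - a) @ v / (v @ v), 0, 1)
                best = min(best, np.linalg.norm(x - (a + t * v)))
            manual += best
        manual *= curve.total_length
        assert spud.curve_objective(pts, curve) == pytest.approx(
            manual, rel=1e-10)


class TestProjection:
    def test_point_on_curve_has_zero_offset_and_correct_arc(self):
        knots = np.array([[0.0, 0], [4, 0], [4, 4], [0, 4]])
        curve = RingCurve(knots=knots)
        assign = spud.project_to_curve(np.array([[2.0, 0.0]]), curve)
        assert abs(assign.offset[0]) < 1e-12
        assert assign.y[0] == pytest.approx(2 / 16)

    def test_tie_breaks_to_lower_segment_index(self):
        knots = np.array([[0.0, 0], [2, 0], [2, 2], [0, 2]])
        curve = RingCurve(knots=knots)
        # the square's center is equidistant from all four segments
        assign = spud.project_to_curve(np.array([[1.0, 1.0]]), curve)
        assert assign.segment[0] == 0

    def test_matches_dense_sampling_oracle(self):
        pts, _ = ring_points(50, r=2.0, noise=0.3, seed=12)
        angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        curve = RingCurve(knots=2.0 * np.c_[np.cos(angles), np.sin(angles)])
        assign = spud.project_to_curve(pts, curve)
        # dense sampling of the curve at 10^4 points
        s = np.linspace(0, 1, 10_000, endpoint=False)
        a, vec = curve.segments
        seg_len = curve.segment_lengths
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        arc = s * curve.total_length
        seg_idx = np.searchsorted(cum, arc, side="right") - 1
        t = (arc - cum[seg_idx]) / seg_len[seg_idx]
        dense = a[seg_idx] + t[:, None] * vec[seg_idx]
        for i, x in enumerate(pts):
            d = np.linalg.norm(dense - x, axis=1)
            j = int(d.argmin())
            assert abs(np.abs(assign.offset[i]) - d[j]) < 1e-3
            assert circular_diff(assign.y[i], s[j]) < 1e-3


class TestAlignment:
    def test_identity_alignment_when_already_matched(self):
        y = np.linspace(0, 1, 350, endpoint=False)
        al = spud.align_coordinates(y, y, n_shift_grid=350)
        assert al.shift == 0.0 and not al.flip
        assert al.objective == pytest.approx(0.0, abs=1e-15)

    def test_flip_detected(self):
        y = np.linspace(0, 1, 350, endpoint=False)
        target = (1.0 - y) % 1.0
        al = spud.align_coordinates(target, y, n_shift_grid=350)
        assert al.flip
        assert al.objective == pytest.approx(0.0, abs=1e-12)

    def test_matches_finer_grid_oracle(self):
        rng = np.random.default_rng(13)
        y = rng.uniform(0, 1, 400)
        t = (y + 0.3123) % 1.0
        coarse = spud.align_coordinates(y, t, n_shift_grid=350)
        fine = spud.align_coordinates(y, t, n_shift_grid=3500)
        assert abs(coarse.objective - fine.objective) < 1e-3
        assert circular_diff(coarse.shift, fine.shift) < 1 / 350


class TestDecoding:
    def test_wraparound_error(self):
        assign = spud.CoordinateAssignment(
            y=np.array([1.0 / 35]), foot=np.zeros((1, 2)),
            tangent=np.ones((1, 2)), offset=np.zeros(1),
            segment=np.zeros(1, dtype=int),
        )
        al = Alignment(shift=0.0, flip=False, objective=0.0)
        res = spud.decode_time(assign, al, np.array([34.0]), period=35.0)
        assert res.decoded_time[0] == pytest.approx(1.0)
        assert res.error[0] == pytest.approx(2.0)
        assert res.error[0] <= 35.0 / 2

    def test_uniform_chance_error_is_period_over_four(self):
        rng = np.random.default_rng(14)
        n = 100_000
        err = circular_diff(rng.uniform(0, 35, n), rng.uniform(0, 35, n),
                            period=35.0)
        assert err.mean() == pytest.approx(35 / 4, abs=0.1)

    def test_summary_matches_stored_errors(self):
        rng = np.random.default_rng(15)
        assign = spud.CoordinateAssignment(
            y=rng.uniform(0, 1, 200), foot=np.zeros((200, 2)),
            tangent=np.ones((200, 2)), offset=np.zeros(200),
            segment=np.zeros(200, dtype=int),
        )
        al = Alignment(shift=0.1, flip=True, objective=0.0)
        res = spud.decode_time(assign, al, rng.uniform(0, 35, 200))
        summary = spud.decoding_error_summary(res)
        assert summary.loc[0, "median_s"] == pytest.approx(
            np.median(res.error))
        assert summary.loc[0, "n"] == 200


class TestEndToEnd:
    def test_noiseless_ring_decodes_below_two_bins(self):
        # points on a circle with time increasing along it: the full SPUD
        # protocol must recover time to well under 0.2 s
        rng = np.random.default_rng(16)
        n = 2000
        tb = rng.integers(0, 350, n)
        theta = 2 * np.pi * (tb + 0.5) / 350
        pts = np.c_[np.cos(theta), np.sin(theta)]
        fit, dec = spud.fit_spud(pts, tb, dt=0.1, seed=0, n_timepoints=350)
        assert np.median(dec.error) < 0.2

    @pytest.mark.parametrize("d", [2, 3, 5])
    def test_decoding_supported_in_higher_embedding_dims(self, d):
        rng = np.random.default_rng(17)
        n = 1200
        tb = rng.integers(0, 350, n)
        theta = 2 * np.pi * (tb + 0.5) / 350
        pts = np.c_[np.cos(theta), np.sin(theta), np.zeros((n, d - 2))]
        pts += 0.03 * rng.normal(size=pts.shape)
        fit, dec = spud.fit_spud(pts, tb, dt=0.1, seed=1, n_timepoints=350)
        assert np.median(dec.error) < 1.0
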