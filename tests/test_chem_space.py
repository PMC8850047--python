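import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemscreen.chem_space import (
    ActiveCurve,
    BoundaryBox,
    ChemSpaceScreen,
    boundary_filter,
    fit_active_curve,
    screen_by_distance,
    shortest_distance,
)
from chemscreen.fixtures import FixturePlan, make_chemspace_fixture


def dense_distance(curve: ActiveCurve, q, n=100_001) -> float:
    """Independent brute-force oracle: min distance over a dense curve grid."""
    xs = np.linspace(curve.domain[0], curve.domain[1], n)
    ys = curve(xs)
    return float(np.sqrt((xs - q[0]) ** 2 + (ys - q[1]) ** 2).min())


class TestPCA:
    def test_line_embedded_in_10d_explains_over_99pct_on_pc1(self, rng):
        t = rng.uniform(-5, 5, 60)
        direction = rng.normal(size=10)
        direction /= np.linalg.norm(direction)
        X = np.outer(t, direction) + rng.normal(0, 1e-4, (60, 10))
        y = np.zeros(60, bool)
        y[:10] = True
        model = ChemSpaceScreen(n_components=3, degree=1, scale=False).fit(X, y)
        assert model.pca_.explained_variance_ratio_[0] > 0.99

    def test_full_rank_projection_reconstructs_scaled_data(self, rng):
        X = rng.normal(size=(30, 6))
        y = np.zeros(30, bool)
        y[:8] = True
        model = ChemSpaceScreen(n_components=6, degree=1).fit(X, y)
        scores = model.transform(X)
        Xs = model.scaler_.transform(X[:, model.keep_mask_])
        recon = scores @ model.pca_.components_ + model.pca_.mean_
        np.testing.assert_allclose(recon, Xs, atol=1e-8)

    def test_explained_variance_non_increasing(self, rng):
        X = rng.normal(size=(40, 12)) * rng.uniform(0.5, 3, 12)
        y = np.zeros(40, bool)
        y[:10] = True
        model = ChemSpaceScreen(n_components=5).fit(X, y)
        evr = model.pca_.explained_variance_ratio_
        assert np.all(np.diff(evr) <= 1e-12)

    def test_n_components_exceeding_rank_raises(self, rng):
        X = rng.normal(size=(5, 4))
        with pytest.raises(ValueError, match="rank"):
            ChemSpaceScreen(n_components=6, degree=1).fit(X, [1, 1, 0, 0, 0])

    def test_too_few_actives_for_curve_raises(self, rng):
        X = rng.normal(size=(10, 5))
        y = np.zeros(10, bool)
        y[:3] = True  # cubic needs 4
        with pytest.raises(ValueError, match="actives"):
            ChemSpaceScreen(degree=3).fit(X, y)


class TestActiveCurve:
    def test_interpolates_exact_cubic(self):
        x = np.linspace(-2, 2, 10)
        curve = fit_active_curve(x, x**3 - 2 * x, degree=3)
        np.testing.assert_allclose(curve.coefficients, [0, -2, 0, 1], atol=1e-8)
        assert curve.domain == (-2.0, 2.0)

    def test_degree_one_matches_simple_regression_formulas(self):
        x = np.array([0.0, 1.0, 3.0])
        y = np.array([1.0, 2.0, 2.5])
        curve = fit_active_curve(x, y, degree=1)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        np.testing.assert_allclose(curve.coefficients, [intercept, slope], atol=1e-12)

    def test_constant_shift_in_y_moves_only_intercept(self, rng):
        x = rng.uniform(-3, 3, 12)
        y = rng.normal(size=12)
        c0 = fit_active_curve(x, y, degree=3).coefficients
        c1 = fit_active_curve(x, y + 5.0, degree=3).coefficients
        assert c1[0] - c0[0] == pytest.approx(5.0, abs=1e-8)
        np.testing.assert_allclose(c0[1:], c1[1:], atol=1e-8)

    def test_insufficient_points_raise(self):
        with pytest.raises(ValueError, match="points"):
            fit_active_curve([0, 1, 2], [0, 1, 2], degree=3)

    def test_endpoints_lie_on_curve(self):
        curve = ActiveCurve((1.0, -0.5, 0.0, 0.1), (-2.0, 2.0))
        assert curve.M == (-2.0, curve(-2.0))
        assert curve.N == (2.0, curve(2.0))


class TestBoundary:
    def test_actives_pass_their_own_box(self, rng):
        pts = rng.normal(size=(16, 3))
        box = BoundaryBox.from_points(pts)
        assert box.contains(pts).all()

    def test_point_epsilon_beyond_max_removed(self):
        box = BoundaryBox((0, 0, 0), (1, 1, 1))
        assert not box.contains([[1 + 1e-9, 0.5, 0.5]])[0]
        assert box.contains([[1.0, 0.5, 0.5]])[0]  # inclusive at the bound

    def test_planted_out_of_box_points_recovered_exactly(self):
        plan = FixturePlan(seed=11, n_unknowns=50, n_out_of_box=5,
                           n_planted_near_curve=7, n_similar=4)
        fx = make_chemspace_fixture(plan)
        box = BoundaryBox.from_points(fx["active_points"].to_numpy())
        pts = fx["unknown_points"].set_index("id")
        kept, removed = boundary_filter(pts, box)
        truth = fx["truth"].set_index("id")["planted"]
        assert set(removed.index) == set(truth.index[truth == "out_of_box"])
        assert len(removed) == 5


class TestShortestDistance:
    flat = ActiveCurve((0.0, 0.0), (-1.0, 1.0))  # y = 0 on [-1, 1]

    def test_point_on_curve_mid_domain_gives_zero_interior(self):
        curve = ActiveCurve((1.0, -0.5, 0.0, 0.1), (-2.0, 2.0))
        res = shortest_distance((0.5, float(curve(0.5))), curve)
        assert res.d_min == pytest.approx(0.0, abs=1e-9)
        assert res.candidate_kind == "interior_root"

    def test_flat_curve_perpendicular_foot(self):
        res = shortest_distance((0.0, 0.5), self.flat)
        assert res.d_min == pytest.approx(0.5)
        assert res.nearest == pytest.approx((0.0, 0.0))

    def test_query_beyond_domain_hits_endpoint(self):
        res = shortest_distance((2.0, 0.0), self.flat)
        assert res.d_min == pytest.approx(1.0)
        assert res.candidate_kind == "endpoint_N"
        assert res.nearest == (1.0, 0.0)
        res_m = shortest_distance((-3.0, 0.0), self.flat)
        assert res_m.candidate_kind == "endpoint_M"

    def test_nearest_point_lies_on_curve(self, rng):
        for _ in range(20):
            curve = ActiveCurve(tuple(rng.normal(size=4)), (-2.0, 2.0))
            q = rng.uniform(-3, 3, 2)
            res = shortest_distance(tuple(q), curve)
            x, y = res.nearest
            assert abs(float(curve(x)) - y) < 1e-9
            assert res.d_min == pytest.approx(np.hypot(x - q[0], y - q[1]), abs=1e-9)

    def test_random_cubics_match_dense_sampling_oracle(self, rng):
        errs = []
        for _ in range(30):
            curve = ActiveCurve(tuple(rng.normal(size=4)), (-2.0, 2.0))
            q = tuple(rng.uniform(-3, 3, 2))
            errs.append(abs(shortest_distance(q, curve).d_min
                            - dense_distance(curve, q)))
        assert max(errs) < 1e-3

    def test_radial_monotonicity_global_for_segment_curve(self, rng):
        # a degree-1 curve is a convex set: distance along the outward ray
        # from the foot is globally non-decreasing
        curve = ActiveCurve((0.3, 0.8), (-2.0, 2.0))
        for _ in range(30):
            q = rng.uniform(-4, 4, 2)
            res = shortest_distance(tuple(q), curve)
            if res.d_min < 1e-9:
                continue
            v = q - np.array(res.nearest)
            prev = res.d_min
            for t in (1.5, 2.0, 4.0, 10.0):
                q2 = np.array(res.nearest) + t * v
                d2 = shortest_distance(tuple(q2), curve).d_min
                assert d2 >= prev - 1e-9
                prev = d2

    def test_radial_monotonicity_local_for_cubic_while_foot_unchanged(self, rng):
        # beyond the medial axis the nearest branch switches, so the
        # guarantee is local: distance grows as long as the foot is the same
        curve = ActiveCurve((0.5, -1.0, 0.2, 0.3), (-2.0, 2.0))
        for _ in range(30):
            q = rng.uniform(-3, 3, 2)
            res = shortest_distance(tuple(q), curve)
            if res.d_min < 1e-9:
                continue
            v = q - np.array(res.nearest)
            prev = res.d_min
            for t in (1.2, 1.5, 2.0, 4.0):
                q2 = np.array(res.nearest) + t * v
                r2 = shortest_distance(tuple(q2), curve)
                if not np.allclose(r2.nearest, res.nearest, atol=1e-6):
                    break
                assert r2.d_min >= prev - 1e-9
                prev = r2.d_min

    def test_uniform_scaling_scales_distance(self):
        curve = ActiveCurve((1.0, -0.5, 0.0, 0.1), (-2.0, 2.0))
        q = (0.7, 2.3)
        d1 = shortest_distance(q, curve).d_min
        for s in (0.5, 3.0):
            # y = p(x) scaled by s in both axes: p_s(x) = s * p(x / s)
            coeffs_s = tuple(c * s ** (1 - k)
                             for k, c in enumerate(curve.coefficients))
            curve_s = ActiveCurve(coeffs_s, (curve.domain[0] * s,
                                             curve.domain[1] * s))
            d_s = shortest_distance((q[0] * s, q[1] * s), curve_s).d_min
            assert d_s == pytest.approx(s * d1, rel=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        coeffs=st.tuples(*[st.floats(-2, 2) for _ in range(4)]),
        qx=st.floats(-3, 3), qy=st.floats(-3, 3),
    )
    def test_distance_bounded_by_endpoint_distances(self, coeffs, qx, qy):
        curve = ActiveCurve(coeffs, (-2.0, 2.0))
        res = shortest_distance((qx, qy), curve)
        d_m = np.hypot(curve.M[0] - qx, curve.M[1] - qy)
        d_n = np.hypot(curve.N[0] - qx, curve.N[1] - qy)
        assert 0 <= res.d_min <= min(d_m, d_n) + 1e-12


class TestScreen:
    def test_threshold_is_strict(self):
        flat = ActiveCurve((0.0, 0.0), (-1.0, 1.0))
        exact = shortest_distance((0.0, 0.2), flat)
        assert exact.d_min == pytest.approx(0.2)
        assert not exact.significant
        assert screen_by_distance([exact], threshold=0.2) == []

    def test_results_sorted_ascending(self):
        flat = ActiveCurve((0.0, 0.0), (-1.0, 1.0))
        res = [shortest_distance((0.0, y), flat) for y in (0.15, 0.05, 0.1)]
        out = screen_by_distance(res, threshold=0.2)
        assert [r.d_min for r in out] == sorted(r.d_min for r in out)
        assert len(out) == 3

    def test_planted_near_curve_points_recovered_exactly(self):
        plan = FixturePlan(seed=5, n_unknowns=40, n_out_of_box=0,
                           n_planted_near_curve=7, n_similar=4)
        fx = make_chemspace_fixture(plan)
        truth = fx["truth"].set_index("id")["planted"]
        res = [
            shortest_distance((r.pc1, r.pc2), fx["curve"], compound_id=r.id)
            for r in fx["unknown_points"].itertuples()
        ]
        hits = {r.compound_id for r in screen_by_distance(res, 0.2)}
        assert hits == set(truth.index[truth == "near"])
        assert len(hits) == 7

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            screen_by_distance([], threshold=0.0)
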