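"""Kernel regression, the linear baseline and bandwidth selection."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from breedopt import (
    SampleSet,
    cv_bandwidth,
    gaussian_kernel,
    linear_baseline_surface,
    nw_estimate,
    smooth_records,
    smooth_surface,
)
from breedopt.evaluation import SyntheticObjective, generate_synthetic_records


class TestGaussianKernel:
    def test_value_at_origin(self):
        assert gaussian_kernel(0.0) == pytest.approx(0.3989423, abs=1e-7)

    @given(st.floats(-30, 30))
    def test_symmetry(self, u):
        assert gaussian_kernel(u) == gaussian_kernel(-u)

    def test_ratio_one_sd_from_origin(self):
        assert gaussian_kernel(1.0) / gaussian_kernel(0.0) == pytest.approx(
            math.exp(-0.5), rel=1e-12
        )


def _brute_force_nw(query, pts, y, h):
    num = den = 0.0
    for i in range(len(y)):
        w = 1.0
        for d in range(len(h)):
            u = (query[d] - pts[i, d]) / h[d]
            w *= math.exp(-0.5 * u * u) / math.sqrt(2 * math.pi)
        num += w * y[i]
        den += w
    return num / den


class TestNWEstimate:
    def test_single_sample_returns_its_response(self):
        ss = SampleSet(np.array([[500.0, 20.0]]), np.array([3.7]))
        est, mass, missing = nw_estimate((100.0, 3.0), ss, (30.0, 1.0))
        assert not missing
        assert est == pytest.approx(3.7)

    def test_equidistant_samples_average(self):
        ss = SampleSet(np.array([[10.0, 0.0], [30.0, 0.0]]), np.array([1.0, 5.0]))
        est, _, _ = nw_estimate((20.0, 0.0), ss, (5.0, 1.0))
        assert est == pytest.approx(3.0)

    def test_matches_double_loop_oracle_in_2d(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 10, size=(20, 2))
        y = rng.standard_normal(20)
        ss = SampleSet(pts, y)
        for _ in range(10):
            q = rng.uniform(0, 10, 2)
            est, _, _ = nw_estimate(q, ss, (1.0, 1.0))
            assert est == pytest.approx(_brute_force_nw(q, pts, y, (1.0, 1.0)), rel=1e-12)

    def test_supports_three_dimensions(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 5, size=(15, 3))
        y = rng.standard_normal(15)
        ss = SampleSet(pts, y)
        q = (2.0, 3.0, 1.0)
        est, _, _ = nw_estimate(q, ss, (1.0, 2.0, 0.5))
        assert est == pytest.approx(_brute_force_nw(q, pts, y, (1.0, 2.0, 0.5)), rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_estimate_is_convex_combination_of_responses(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 30)
        pts = rng.uniform(-5, 5, size=(n, 2))
        y = rng.standard_normal(n)
        est, _, missing = nw_estimate(
            rng.uniform(-5, 5, 2), SampleSet(pts, y), rng.uniform(0.3, 3.0, 2)
        )
        if not missing:
            assert y.min() - 1e-9 <= est <= y.max() + 1e-9

    def test_underflow_flags_missing(self):
        ss = SampleSet(np.array([[0.0, 0.0]]), np.array([1.0]))
        est, mass, missing = nw_estimate((1e6, 1e6), ss, (1.0, 1.0))
        assert missing and math.isnan(est)


class TestSmoothSurface:
    def test_lattice_fast_path_matches_pointwise_estimates(self):
        rng = np.random.default_rng(3)
        pts = rng.integers(0, 30, size=(200, 2)).astype(float)
        y = rng.standard_normal(200)
        ss = SampleSet(pts, y)
        axes = (np.arange(0.0, 30.0), np.arange(0.0, 10.0))
        surf = smooth_surface(ss, axes, (4.0, 2.0), mass_floor_rel=0.0)
        for i in [0, 7, 29]:
            for j in [0, 4, 9]:
                est, _, _ = nw_estimate((axes[0][i], axes[1][j]), ss, (4.0, 2.0))
                assert surf.estimate[i, j] == pytest.approx(est, rel=1e-10)

    def test_constant_responses_give_constant_surface(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 100, size=(50, 2))
        surf = smooth_surface(
            SampleSet(pts, np.full(50, 2.5)),
            (np.linspace(0, 100, 11), np.linspace(0, 100, 11)),
            (10.0, 10.0),
        )
        assert np.allclose(surf.estimate[~surf.missing], 2.5)

    def test_huge_bandwidth_recovers_global_mean(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 100, size=(60, 2))
        y = rng.standard_normal(60)
        surf = smooth_surface(
            SampleSet(pts, y), (np.linspace(0, 100, 5), np.linspace(0, 100, 5)),
            (1e6, 1e6),
        )
        assert np.allclose(surf.estimate, y.mean(), atol=1e-6)

    def test_invariant_to_sample_ordering(self):
        rng = np.random.default_rng(6)
        pts = rng.integers(0, 50, size=(300, 2)).astype(float)
        y = rng.standard_normal(300)
        axes = (np.arange(0.0, 50.0, 5.0), np.arange(0.0, 50.0, 5.0))
        a = smooth_surface(SampleSet(pts, y), axes, (5.0, 5.0))
        perm = rng.permutation(300)
        b = smooth_surface(SampleSet(pts[perm], y[perm]), axes, (5.0, 5.0))
        assert np.allclose(a.estimate, b.estimate, equal_nan=True)

    def test_noiseless_linear_function_recovered_in_interior(self):
        # full lattice of samples: symmetric kernel weights leave a
        # linear function unbiased away from the boundary
        g2, g3 = np.meshgrid(np.arange(0.0, 41.0), np.arange(0.0, 41.0), indexing="ij")
        pts = np.column_stack([g2.ravel(), g3.ravel()])
        y = 0.3 * pts[:, 0] - 0.7 * pts[:, 1]
        axes = (np.arange(15.0, 26.0), np.arange(15.0, 26.0))
        surf = smooth_surface(SampleSet(pts, y), axes, (2.0, 2.0))
        truth = 0.3 * surf.x2[:, None] - 0.7 * surf.x3[None, :]
        assert np.max(np.abs(surf.estimate - truth)) < 1e-6

    def test_matches_statsmodels_local_constant_regression(self):
        sm_nonparam = pytest.importorskip("statsmodels.nonparametric.kernel_regression")
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 10, size=(80, 2))
        y = np.sin(pts[:, 0]) + 0.1 * rng.standard_normal(80)
        ss = SampleSet(pts, y)
        h = (1.2, 2.0)
        kr = sm_nonparam.KernelReg(y, pts, var_type="cc", reg_type="lc", bw=list(h))
        queries = rng.uniform(1, 9, size=(10, 2))
        mean, _ = kr.fit(queries)
        for q, expected in zip(queries, mean):
            est, _, _ = nw_estimate(q, ss, h)
            assert est == pytest.approx(expected, rel=1e-8)


class TestSmoothRecords:
    def test_composite_surface_composes_separately_smoothed_responses(
        self, quadratic_objective, bounds, budget
    ):
        recs = generate_synthetic_records(quadratic_objective, 500, bounds, budget, seed=8)
        axes = (np.arange(300.0, 501.0, 10.0), np.arange(10.0, 21.0))
        bundle = smooth_records(recs, axes, h_g=(30.0, 1.0), f_divisor=3.0)
        ok = ~bundle.m.missing
        assert np.allclose(
            bundle.m.estimate[ok],
            bundle.g.estimate[ok] - 50.0 * bundle.f.estimate[ok],
        )

    def test_direct_smoothing_of_m_realizations(self, quadratic_objective, bounds, budget):
        recs = generate_synthetic_records(quadratic_objective, 500, bounds, budget, seed=8)
        axes = (np.arange(300.0, 501.0, 10.0), np.arange(10.0, 21.0))
        direct = smooth_records(recs, axes, compose=False)
        ok = ~direct.m.missing
        # direct m-smoothing uses the g bandwidths on m realizations
        from breedopt.smoothing import smooth_surface as ssurf

        ref = ssurf(
            SampleSet(recs[["x2", "x3"]].to_numpy(float), recs["m"].to_numpy()),
            axes, (30.0, 1.0),
        )
        assert np.allclose(direct.m.estimate[ok], ref.estimate[ok])


class TestLinearBaseline:
    def test_interpolates_sample_locations_after_duplicate_averaging(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        y = np.array([1.0, 3.0, 5.0, 7.0])
        surf = linear_baseline_surface(
            SampleSet(pts, y), (np.array([0.0, 10.0]), np.array([0.0, 10.0]))
        )
        assert surf.at(0.0, 0.0) == pytest.approx(2.0)  # mean of the duplicates
        assert surf.at(10.0, 0.0) == pytest.approx(5.0)

    def test_centroid_of_triangle_is_barycentric_mean(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]])
        y = np.array([0.0, 0.0, 3.0])
        surf = linear_baseline_surface(
            SampleSet(pts, y), (np.array([1.0]), np.array([1.0]))
        )
        assert surf.at(1.0, 1.0) == pytest.approx(1.0)

    def test_exactly_recovers_linear_functions_inside_hull(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 20, size=(40, 2))
        y = 2.0 + 0.5 * pts[:, 0] - 1.5 * pts[:, 1]
        axes = (np.arange(5.0, 16.0), np.arange(5.0, 16.0))
        surf = linear_baseline_surface(SampleSet(pts, y), axes)
        truth = 2.0 + 0.5 * surf.x2[:, None] - 1.5 * surf.x3[None, :]
        ok = ~surf.missing
        assert np.allclose(surf.estimate[ok], truth[ok], atol=1e-9)

    def test_points_outside_hull_are_flagged_missing(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        surf = linear_baseline_surface(
            SampleSet(pts, np.ones(3)), (np.array([1.0, 50.0]), np.array([1.0, 50.0]))
        )
        assert not surf.missing[0, 0] and surf.missing[1, 1]

    def test_collinear_geometry_raises(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError, match="degenerate"):
            linear_baseline_surface(
                SampleSet(pts, np.ones(4)), (np.array([1.0]), np.array([1.0]))
            )

    def test_nw_beats_linear_interpolation_on_noisy_surfaces(self, bounds, budget):
        # the baseline chases noise spikes; kernel regression averages
        # them out (a gently curved truth keeps NW's smoothing bias small
        # relative to the noise the baseline interpolates verbatim)
        obj = SyntheticObjective.quadratic(curvature=(0.0005, 0.1))
        axes = (np.arange(150.0, 651.0, 10.0), np.arange(5.0, 29.0))
        truth = obj.true_m(axes[0][:, None], axes[1][None, :])
        wins = 0
        for rep in range(20):
            recs = generate_synthetic_records(obj, 1500, bounds, budget, seed=100 + rep)
            ss = SampleSet(recs[["x2", "x3"]].to_numpy(float), recs["m"].to_numpy())
            nw = smooth_surface(ss, axes, (30.0, 1.0))
            lin = linear_baseline_surface(ss, axes)
            ok = ~(nw.missing | lin.missing)
            mse_nw = np.mean((nw.estimate[ok] - truth[ok]) ** 2)
            mse_lin = np.mean((lin.estimate[ok] - truth[ok]) ** 2)
            wins += mse_nw < mse_lin
        assert wins >= 15


class TestCVBandwidth:
    @staticmethod
    def _quadratic_samples(n, noise, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-5, 5, size=(n, 2))
        y = -(pts**2).sum(axis=1) + noise * rng.standard_normal(n)
        return SampleSet(pts, y)

    def test_single_candidate_is_returned(self):
        ss = self._quadratic_samples(20, 0.0, 0)
        assert cv_bandwidth(ss, [(2.0, 2.0)]) == (2.0, 2.0)

    def test_noiseless_smooth_function_rejects_oversmoothing(self):
        ss = self._quadratic_samples(80, 0.0, 1)
        chosen = cv_bandwidth(ss, [(0.3, 0.3), (1.5, 1.5), (500.0, 500.0)])
        assert chosen != (500.0, 500.0)

    def test_pure_noise_prefers_the_largest_bandwidth(self):
        votes = 0
        for seed in range(7):
            rng = np.random.default_rng(1000 + seed)
            pts = rng.uniform(-5, 5, size=(120, 2))
            ss = SampleSet(pts, rng.standard_normal(120))
            chosen = cv_bandwidth(ss, [(0.3, 0.3), (1.0, 1.0), (50.0, 50.0)])
            votes += chosen == (50.0, 50.0)
        assert votes >= 4

    def test_kfold_used_above_threshold_is_deterministic(self):
        ss = self._quadratic_samples(120, 0.5, 3)
        cands = [(0.5, 0.5), (2.0, 2.0)]
        a = cv_bandwidth(ss, cands, loo_max_n=50, seed=7)
        b = cv_bandwidth(ss, cands, loo_max_n=50, seed=7)
        assert a == b

    def test_too_few_samples_rejected(self):
        ss = self._quadratic_samples(5, 0.0, 4)
        with pytest.raises(ValueError):
            cv_bandwidth(ss, [(1.0, 1.0), (2.0, 2.0)])
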