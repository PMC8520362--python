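"""Kernel, design-matrix and weighted least-squares primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonokr import (
    BASIS_SIZE,
    DomainError,
    EmptyNeighborhoodError,
    KernelSpec,
    PointCloud,
    build_design,
    fit_local,
    gaussian_kernel,
    local_weights,
)


class TestGaussianKernel:
    def test_maximal_at_origin_and_symmetric(self):
        h = 2.0
        k0 = gaussian_kernel((0.0, 0.0, 0.0), h)
        u = np.array([1.0, 2.0, 3.0])
        assert gaussian_kernel(u, h) == gaussian_kernel(-u, h)
        assert k0 == 1.0
        for off in np.random.default_rng(3).normal(size=(20, 3)):
            assert 0.0 < gaussian_kernel(off, h) <= k0

    def test_one_bandwidth_offset_ratio(self):
        # K((h,0,0)) / K(0) = exp(-1/2)
        h = 1.7
        ratio = gaussian_kernel((h, 0.0, 0.0), h) / gaussian_kernel((0.0, 0.0, 0.0), h)
        assert ratio == pytest.approx(np.exp(-0.5), rel=1e-12)

    @pytest.mark.parametrize("h", [0.0, -1.0, np.nan])
    def test_invalid_bandwidth_rejected(self, h):
        with pytest.raises(DomainError):
            gaussian_kernel((1.0, 0.0, 0.0), h)

    def test_nonfinite_offset_rejected(self):
        with pytest.raises(DomainError):
            gaussian_kernel((np.inf, 0.0, 0.0), 1.0)


class TestLocalWeights:
    def test_coincident_neighbor_dominates_and_isotropy(self):
        center = np.array([1.0, -2.0, 0.5])
        nb = np.array([center, center + [1, 0, 0], center + [0, 0, -1], center + [2, 0, 0]])
        w = local_weights(center, nb, h=1.0)
        assert np.argmax(w) == 0
        assert w[1] == pytest.approx(w[2], rel=1e-14)  # equal distance, any direction

    def test_distance_ratio(self):
        # distances 1 and 2 at h=1: weight ratio exp(1.5)
        w = local_weights([0, 0, 0], [[1, 0, 0], [0, 2, 0]], h=1.0)
        assert w[0] / w[1] == pytest.approx(np.exp(1.5), rel=1e-12)

    def test_empty_neighbors_rejected(self):
        with pytest.raises(EmptyNeighborhoodError):
            local_weights([0, 0, 0], np.empty((0, 3)), h=1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_weights_strictly_decrease_with_distance(self, seed):
        rng = np.random.default_rng(seed)
        center = rng.normal(size=3)
        nb = center + rng.normal(size=(12, 3))
        h = float(rng.uniform(0.3, 3.0))
        w = local_weights(center, nb, h)
        d = np.linalg.norm(nb - center, axis=1)
        order = np.argsort(d)
        dd, ww = d[order], w[order]
        strict = np.diff(dd) > 1e-12
        assert np.all(np.diff(ww)[strict] < 0)


class TestBuildDesign:
    def test_order1_row_is_one_and_offsets(self):
        row = build_design([1.0, 2.0, 3.0], [[1.5, 1.0, 3.25]], order_N=1)
        np.testing.assert_allclose(row, [[1.0, 0.5, -1.0, 0.25]])

    def test_order0_single_ones_column(self):
        d = build_design([0, 0, 0], np.random.default_rng(0).normal(size=(7, 3)), 0)
        np.testing.assert_array_equal(d, np.ones((7, 1)))

    def test_order2_has_ten_columns(self):
        # monomials of degree <= 2 in 3 variables: C(5, 2) = 10
        d = build_design([0, 0, 0], np.random.default_rng(0).normal(size=(5, 3)), 2)
        assert d.shape == (5, 10)
        off = np.array([[0.5, -1.0, 2.0]])
        row = build_design([0, 0, 0], off, 2)[0]
        np.testing.assert_allclose(
            row, [1, 0.5, -1, 2, 0.25, 1, 4, -0.5, 1, -2], rtol=1e-14
        )

    def test_invalid_order_rejected(self):
        with pytest.raises(DomainError):
            build_design([0, 0, 0], [[1, 1, 1]], 3)


def _brute_force_wls(design, weights, values):
    """Independent oracle: QR/SVD least squares on the sqrt-weighted system
    (never the normal equations used by the implementation)."""
    sw = np.sqrt(np.asarray(weights, float))
    beta, *_ = np.linalg.lstsq(sw[:, None] * design, sw * values, rcond=None)
    return beta


class TestFitLocal:
    def test_constant_values_reproduced(self):
        nb = np.random.default_rng(1).normal(size=(6, 3))
        d = build_design([0, 0, 0], nb, 1)
        w = local_weights([0, 0, 0], nb, 1.0)
        fit = fit_local(d, w, np.full(6, 4.25))
        assert fit.estimate == pytest.approx(4.25, abs=1e-10)
        np.testing.assert_allclose(fit.beta[1:], 0.0, atol=1e-9)

    def test_affine_field_recovered_exactly(self):
        rng = np.random.default_rng(2)
        nb = rng.normal(size=(9, 3))
        vals = 2.0 + nb @ [3.0, -1.0, 0.5]
        d = build_design([0, 0, 0], nb, 1)
        w = local_weights([0, 0, 0], nb, 0.8)
        fit = fit_local(d, w, vals)
        np.testing.assert_allclose(fit.beta, [2.0, 3.0, -1.0, 0.5], atol=1e-9)
        # zero residual at the sample points
        np.testing.assert_allclose(d @ fit.beta, vals, atol=1e-9)

    def test_matches_brute_force_oracle_on_seeded_instances(self):
        # 100 random small instances against an independent solver
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(6, 15))
            order = int(rng.integers(0, 3))
            if n < BASIS_SIZE[order] + 2:
                n = BASIS_SIZE[order] + 2
            nb = rng.normal(size=(n, 3))
            vals = rng.normal(size=n)
            d = build_design([0, 0, 0], nb, order)
            w = local_weights([0, 0, 0], nb, float(rng.uniform(0.5, 2.0)))
            fit = fit_local(d, w, vals)
            expected = _brute_force_wls(d, w, vals)
            np.testing.assert_allclose(
                fit.beta, expected, rtol=1e-10, atol=1e-10 * np.linalg.norm(expected)
            )

    def test_all_zero_weights_rejected(self):
        d = build_design([0, 0, 0], [[1, 0, 0], [0, 1, 0]], 0)
        with pytest.raises(EmptyNeighborhoodError):
            fit_local(d, [0.0, 0.0], [1.0, 2.0])

    def test_nonfinite_values_rejected(self):
        d = build_design([0, 0, 0], [[1, 0, 0], [0, 1, 0]], 0)
        with pytest.raises(DomainError):
            fit_local(d, [1.0, 1.0], [np.nan, 2.0])

    def test_rank_deficient_system_falls_back_to_ridge(self):
        # three collinear points cannot support a full linear fit
        nb = np.array([[1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0], [4.0, 0, 0]])
        d = build_design([0, 0, 0], nb, 1)
        w = np.ones(4)
        fit = fit_local(d, w, nb[:, 0] * 2.0, ridge_eps=1e-10)
        assert fit.ridge_applied
        assert np.all(np.isfinite(fit.beta))


class TestSpecsAndTypes:
    def test_kernel_spec_validation(self):
        with pytest.raises(DomainError):
            KernelSpec(bandwidth_h=0.0)
        with pytest.raises(DomainError):
            KernelSpec(bandwidth_h=1.0, order_N=3)
        with pytest.raises(DomainError):
            KernelSpec(bandwidth_h=1.0, support_radius_factor=0.5)
        spec = KernelSpec(bandwidth_h=2.0)
        assert spec.support_radius == 6.0
        assert spec.second_moment_c == 4.0

    def test_point_cloud_validation(self):
        with pytest.raises(DomainError):
            PointCloud(positions=np.zeros((2, 3)), values=np.zeros(3))
        with pytest.raises(DomainError):
            PointCloud(positions=np.array([[np.inf, 0, 0]]), values=np.array([1.0]))
        cloud = PointCloud(positions=np.zeros((4, 3)), values=np.arange(4.0))
        assert cloud.count == len(cloud) == 4
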