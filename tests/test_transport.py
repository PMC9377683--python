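import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from otmorph import (
    ConvergenceReport,
    DensityMap,
    TransportParams,
    apply_kernel,
    barycenter,
    dense_transport_oracle,
    gamma_from_angstrom2,
    sinkhorn_distance,
    to_probability,
)
from otmorph.errors import GridMismatchError, IllConditionedKernelWarning

from conftest import centroid


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gamma": 0.0},
            {"gamma": -1.0},
            {"max_iter": 0},
            {"tol": 0.0},
            {"floor": 0.0},
            {"truncation_radius": 2.0},
            {"kernel_convention": "gaussian"},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TransportParams(**kwargs)

    def test_sigma_conventions(self):
        assert TransportParams(gamma=4.0).sigma == pytest.approx(2.0)
        assert TransportParams(gamma=4.0, kernel_convention="standard").sigma == (
            pytest.approx(math.sqrt(2.0))
        )

    def test_angstrom_conversion(self):
        # 8 Å² at a 2 Å voxel is 2 voxel²
        assert gamma_from_angstrom2(8.0, 2.0) == pytest.approx(2.0)

    def test_report_length_invariant(self):
        with pytest.raises(ValueError):
            ConvergenceReport(iterations_used=3, change_history=[1.0], converged=False)


class TestApplyKernel:
    def test_matches_dense_kernel_column(self):
        # a unit voxel picks out one column of the dense Gibbs kernel
        field = np.zeros((9, 9, 9))
        field[4, 4, 4] = 1.0
        out = apply_kernel(field, gamma=1.0, convention="standard")
        coords = np.indices((9, 9, 9)).reshape(3, -1).T.astype(float)
        d2 = cdist(coords, [[4.0, 4.0, 4.0]], "sqeuclidean").ravel()
        expected = np.exp(-d2).reshape(9, 9, 9)
        assert np.allclose(out, expected, atol=1e-6)

    def test_gaussian_semigroup(self):
        # K_g1 K_g2 = c * K_{g1+g2}: convolving unnormalized Gaussians picks
        # up the constant (2*pi*s1^2*s2^2/(s1^2+s2^2))^{3/2}
        rng = np.random.default_rng(5)
        field = np.zeros((25, 25, 25))
        field[10:15, 10:15, 10:15] = rng.random((5, 5, 5))
        # sigmas > 1 voxel keep the discrete-sampling aliasing error below
        # the comparison tolerance (it scales like exp(-2*pi^2*sigma^2))
        g1, g2 = 2.0, 3.0
        twice = apply_kernel(apply_kernel(field, g1), g2)
        once = apply_kernel(field, g1 + g2)
        const = (2.0 * math.pi * g1 * g2 / (g1 + g2)) ** 1.5
        interior = (slice(6, 19),) * 3
        assert np.allclose(twice[interior], const * once[interior], rtol=1e-6)

    def test_symmetry_preserved(self):
        field = np.zeros((11, 11, 11))
        field[5, 5, 5] = 2.0
        for offset in (3, 7):  # six-point star: symmetric under axis swaps too
            field[offset, 5, 5] = field[5, offset, 5] = field[5, 5, offset] = 1.0
        out = apply_kernel(field, gamma=1.5)
        assert np.allclose(out, out[::-1, :, :])
        assert np.allclose(out, np.transpose(out, (2, 1, 0)))

    def test_small_sigma_warns(self):
        with pytest.warns(IllConditionedKernelWarning):
            apply_kernel(np.ones((8, 8, 8)), gamma=0.05, convention="standard")


class TestSinkhornDistance:
    def test_symmetric_in_arguments(self, random_pair_6):
        p, q = random_pair_6
        params = TransportParams(gamma=1.0, tol=1e-12)
        wpq, _ = sinkhorn_distance(p, q, params)
        wqp, _ = sinkhorn_distance(q, p, params)
        assert wpq == pytest.approx(wqp, abs=1e-9)

    def test_point_mass_limit(self):
        # at gamma -> 0 the cost of two unit point masses tends to d^2 = 9
        g = np.zeros((11, 11, 11))
        h = np.zeros((11, 11, 11))
        g[4, 5, 5] = 1.0
        h[7, 5, 5] = 1.0
        p, q = to_probability(DensityMap(g)), to_probability(DensityMap(h))
        with pytest.warns(IllConditionedKernelWarning):
            w2sq, _ = sinkhorn_distance(
                p, q, TransportParams(gamma=0.05, kernel_convention="standard", tol=1e-12)
            )
        assert w2sq == pytest.approx(9.0, rel=0.05)

    @pytest.mark.parametrize("gamma", [0.5, 1.0, 2.0])
    def test_matches_dense_oracle(self, random_pair_6, gamma):
        p, q = random_pair_6
        w_conv, _ = sinkhorn_distance(
            p,
            q,
            TransportParams(
                gamma=gamma, kernel_convention="standard", tol=1e-12, max_iter=5000
            ),
        )
        w_dense, _ = dense_transport_oracle(p, q, gamma)
        assert abs(w_conv - w_dense) / abs(w_dense) <= 1e-3

    def test_grid_mismatch(self, random_pair_6):
        p, _ = random_pair_6
        other = to_probability(DensityMap(np.ones((5, 5, 5))))
        with pytest.raises(GridMismatchError):
            sinkhorn_distance(p, other)


class TestBarycenter:
    def test_degenerate_weight_recovers_input(self, two_blob_32):
        a, b = two_blob_32
        pa, pb = to_probability(a), to_probability(b)
        bary, _ = barycenter([pa, pb], [1.0, 0.0], TransportParams(gamma=1.0))
        corr = np.corrcoef(bary.data.ravel(), pa.data.ravel())[0, 1]
        assert corr >= 0.99
        assert np.linalg.norm(centroid(bary.data) - centroid(pa.data)) <= 0.25

    @pytest.mark.parametrize("t", [0.25, 0.5, 0.75])
    def test_centroid_linearity(self, two_blob_32, t):
        a, b = two_blob_32
        pa, pb = to_probability(a), to_probability(b)
        bary, report = barycenter([pa, pb], [1.0 - t, t], TransportParams(gamma=1.0))
        assert report.converged
        expected = (1 - t) * centroid(pa.data) + t * centroid(pb.data)
        assert np.linalg.norm(centroid(bary.data) - expected) <= 0.25

    def test_order_symmetry(self, two_blob_32):
        a, b = two_blob_32
        pa, pb = to_probability(a), to_probability(b)
        params = TransportParams(gamma=1.0, tol=1e-10)
        f1, _ = barycenter([pa, pb], [0.7, 0.3], params)
        f2, _ = barycenter([pb, pa], [0.3, 0.7], params)
        assert np.abs(f1.data - f2.data).max() <= 1e-8

    def test_unit_mass_output(self, two_blob_32):
        a, b = two_blob_32
        pa, pb = to_probability(a), to_probability(b)
        bary, _ = barycenter([pa, pb], [0.3, 0.7], TransportParams(gamma=2.0))
        assert abs(bary.data.sum() - 1.0) <= 1e-9
        assert np.all(bary.data >= 0)

    def test_endpoint_continuity(self, two_blob_32):
        # barycenter at weights (1-eps, eps) approaches the weight-(1,0)
        # solution monotonically as eps shrinks
        a, b = two_blob_32
        pa, pb = to_probability(a), to_probability(b)
        params = TransportParams(gamma=1.0, tol=1e-10)
        ref, _ = barycenter([pa, pb], [1.0, 0.0], params)
        gaps = []
        for eps in (0.1, 0.01, 0.001):
            bary, _ = barycenter([pa, pb], [1.0 - eps, eps], params)
            gaps.append(np.linalg.norm(bary.data - ref.data))
        assert gaps[0] > gaps[1] > gaps[2]

    def test_smoothing_increases_with_gamma(self, two_blob_32):
        # spatial variance of the isobarycenter grows with regularization
        a, b = two_blob_32
        pa, pb = to_probability(a), to_probability(b)
        variances = []
        for gamma in (0.5, 1.0, 2.0, 3.0):
            bary, _ = barycenter([pa, pb], [0.5, 0.5], TransportParams(gamma=gamma))
            c = centroid(bary.data)
            idx = np.indices(bary.shape)
            var = sum(((idx[i] - c[i]) ** 2 * bary.data).sum() for i in range(3))
            variances.append(var)
        assert all(v2 >= v1 for v1, v2 in zip(variances, variances[1:]))

    def test_change_history_eventually_decreasing(self, two_blob_32):
        a, b = two_blob_32
        pa, pb = to_probability(a), to_probability(b)
        _, report = barycenter([pa, pb], [0.5, 0.5], TransportParams(gamma=1.0))
        tail = report.change_history[len(report.change_history) // 2 :]
        assert all(c2 <= c1 for c1, c2 in zip(tail, tail[1:]))
        assert report.converged
        assert len(report.change_history) == report.iterations_used

    @pytest.mark.parametrize(
        "weights", [[0.5, 0.6], [-0.1, 1.1], [0.5, 0.25, 0.25]]
    )
    def test_invalid_weights(self, two_blob_32, weights):
        a, b = two_blob_32
        pa, pb = to_probability(a), to_probability(b)
        with pytest.raises((ValueError, GridMismatchError)):
            barycenter([pa, pb], weights)

    def test_three_measure_barycenter_mass(self):
        # k-measure path: equal-weight barycenter of three blobs keeps mass 1
        from otmorph import BlobSpec, blob_map

        maps = [
            blob_map((20, 20, 20), [BlobSpec(c, sigma=1.5)])
            for c in [(6, 6, 10), (14, 6, 10), (10, 14, 10)]
        ]
        ps = [to_probability(m) for m in maps]
        bary, _ = barycenter(ps, [1 / 3] * 3, TransportParams(gamma=1.0))
        assert abs(bary.data.sum() - 1.0) <= 1e-9
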