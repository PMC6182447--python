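import numpy as np
import pytest

from plmdiff import (
    PLMData,
    Partition,
    ReproducingKernel,
    build_scaling_function,
    choose_resolution,
    fit_nonparametric,
    kernel_eval,
    kernel_weights,
    tau2_t_plugin,
)
from plmdiff.wavelet_estimator import ScalingFunction


@pytest.fixture(scope="module")
def db2():
    return build_scaling_function("daubechies-2", 10)


class TestScalingFunction:
    def test_haar_is_unit_indicator(self):
        phi = build_scaling_function("haar")
        assert phi(np.array([0.0, 0.5, 0.99])).tolist() == [1.0, 1.0, 1.0]
        assert phi(np.array([-0.1, 1.0, 2.0])).tolist() == [0.0, 0.0, 0.0]

    @pytest.mark.parametrize("family", ["daubechies-2", "daubechies-3"])
    def test_integrates_to_one(self, family):
        phi = build_scaling_function(family, 10)
        assert abs(np.trapezoid(phi.values, phi.grid) - 1.0) <= 1e-6

    def test_haar_integrates_to_one(self):
        # the table has a jump at 1, so trapezoid loses half a grid step;
        # the exact indicator integrates to 1
        phi = build_scaling_function("haar")
        assert abs(np.trapezoid(phi.values, phi.grid) - 1.0) <= phi.grid_step
        u = (np.arange(4096) + 0.5) / 4096  # midpoint rule, exact for a step
        assert phi(u).mean() == pytest.approx(1.0, abs=1e-12)

    def test_db2_partition_of_unity(self, db2):
        # sum_k phi(t - k) = 1 on interior points of the support union
        t = np.linspace(1.0, 2.0, 257)
        total = sum(db2(t - k) for k in range(-2, 4))
        assert np.abs(total - 1.0).max() <= 1e-4

    def test_compact_support(self, db2):
        assert db2.support == (0.0, 3.0)
        assert db2(np.array([-0.5, 3.5])).tolist() == [0.0, 0.0]

    def test_unknown_family_lists_supported(self):
        with pytest.raises(ValueError, match="haar"):
            build_scaling_function("coiflet-9")

    def test_refinement_floor_for_daubechies(self):
        with pytest.raises(ValueError):
            build_scaling_function("daubechies-2", refinement=4)


class TestChooseResolution:
    @pytest.mark.parametrize(
        "n,expected", [(8, 1), (64, 2), (128, 3), (256, 3), (512, 3), (513, 4)]
    )
    def test_smallest_dyadic_cover_of_cube_root(self, n, expected):
        assert choose_resolution(n) == expected
        # the defining property: 2^m >= n^(1/3) > 2^(m-1) (up to m = 1)
        m = choose_resolution(n)
        assert 2**m >= n ** (1 / 3) - 1e-9

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            choose_resolution(7)


class TestKernelEval:
    def test_haar_dyadic_bins(self):
        kern = ReproducingKernel(build_scaling_function("haar"), 2)
        # same quarter of [0,1): 2^m = 4; different quarters: 0
        assert kernel_eval(kern, 0.1, 0.2) == pytest.approx(4.0)
        assert kernel_eval(kern, 0.1, 0.3) == pytest.approx(0.0)
        assert kernel_eval(kern, 0.8, 0.99) == pytest.approx(4.0)

    def test_symmetry(self, db2, rng):
        kern = ReproducingKernel(db2, 3)
        t = rng.uniform(size=50)
        s = rng.uniform(size=50)
        np.testing.assert_allclose(
            kernel_eval(kern, t, s), kernel_eval(kern, s, t), atol=1e-10
        )

    def test_locality(self, db2):
        kern = ReproducingKernel(db2, 3)
        # E(t,s) = 0 when |t-s| > support_width * 2^-m = 3/8
        assert kernel_eval(kern, 0.1, 0.6) == 0.0
        assert kernel_eval(kern, 0.0, 1.0) == 0.0

    def test_sup_bound_scales_with_resolution(self, db2):
        # |E_m| = O(2^m): the normalized sup stays below a single constant
        grid = np.linspace(0, 1, 101)
        tt, ss = np.meshgrid(grid, grid)
        for m in range(1, 5):
            kern = ReproducingKernel(db2, m)
            sup = np.abs(kernel_eval(kern, tt.ravel(), ss.ravel())).max()
            assert sup <= 2.1 * 2**m

    def test_l1_bound_uniform_in_resolution(self, db2):
        # sup_t int_0^1 |E_m(t,s)| ds stays below one constant across m
        s = np.linspace(0, 1, 2001)
        for m in range(1, 6):
            kern = ReproducingKernel(db2, m)
            worst = max(
                np.trapezoid(np.abs(kernel_eval(kern, np.full_like(s, t), s)), s)
                for t in np.linspace(0, 1, 41)
            )
            assert worst <= 2.0

    def test_domain_check(self, db2):
        kern = ReproducingKernel(db2, 2)
        with pytest.raises(ValueError):
            kernel_eval(kern, 1.2, 0.5)


class TestPartition:
    def test_uniform_satisfies_mesh_condition(self):
        p = Partition.uniform(100)
        assert p.n == 100
        assert p.check_spacing(C=1.5)
        assert p.contains(np.arange(1, 101) / 100)

    def test_invalid_partitions_rejected(self):
        with pytest.raises(ValueError):
            Partition(np.array([0.0, 0.5, 0.4, 1.0]))
        with pytest.raises(ValueError):
            Partition(np.array([0.1, 1.0]))


class TestKernelWeights:
    def test_haar_closed_form_uniform(self):
        kern = ReproducingKernel(build_scaling_function("haar"), 2)
        w = kernel_weights(kern, Partition.uniform(16), t=0.3)
        # t = 0.3 is in bin [0.25, 0.5); the 4 intervals there get 4/16 each
        expected = np.zeros(16)
        expected[4:8] = 0.25
        np.testing.assert_allclose(w, expected, atol=1e-14)
        assert w.sum() == pytest.approx(1.0)

    def test_haar_quadrature_matches_closed_form_on_dyadic_partition(self):
        # quadrature is exact when every interval lies inside one dyadic bin
        closed = build_scaling_function("haar")
        table = ScalingFunction(
            family="haar-by-quadrature",
            grid=closed.grid,
            values=closed.values,
            support=closed.support,
            grid_step=closed.grid_step,
            exact=closed.exact,
        )
        # t = 1.0 excluded: the half-open dyadic indicator makes E(1, s) = 0,
        # whereas the closed form assigns t = 1 to the last bin
        part = Partition.uniform(16)
        for t in (0.0, 0.3, 0.71, 0.99):
            w_closed = kernel_weights(ReproducingKernel(closed, 2), part, t)
            w_quad = kernel_weights(ReproducingKernel(table, 2), part, t)
            np.testing.assert_allclose(w_quad, w_closed, atol=1e-8)

    def test_quadrature_against_refined_trapezoid(self, db2):
        kern = ReproducingKernel(db2, 2)
        part = Partition.uniform(32)
        w = kernel_weights(kern, part, t=0.37)
        b = part.breakpoints
        oracle = np.array([
            np.trapezoid(
                kernel_eval(kern, np.full(801, 0.37), np.linspace(b[i], b[i + 1], 801)),
                np.linspace(b[i], b[i + 1], 801),
            )
            for i in range(32)
        ])
        # the tabulated scaling function is piecewise linear, so fixed-order
        # quadrature and a refined trapezoid agree to ~1e-4, not machine precision
        np.testing.assert_allclose(w, oracle, atol=1e-3)

    def test_weights_normalize_in_the_interior(self, db2):
        for m, n in [(2, 128), (3, 128), (3, 512)]:
            w = kernel_weights(ReproducingKernel(db2, m), Partition.uniform(n), 0.5)
            assert abs(w.sum() - 1.0) <= 0.05


class TestFitNonparametric:
    def test_constant_residuals_reproduced(self, db2):
        n = 64
        t = np.arange(1, n + 1) / n
        c = 2.5
        data = PLMData(y=np.full(n, c), X=np.zeros((n, 1)), t=t)
        kern = ReproducingKernel(db2, 2)
        fit = fit_nonparametric(data, np.array([0.0]), kern, Partition.uniform(n), [0.5])
        assert fit.f_hat[0] == pytest.approx(c, rel=1e-6)

    def test_haar_gives_dyadic_bin_average(self, rng):
        n, m = 16, 2
        t = np.arange(1, n + 1) / n
        y = rng.normal(size=n)
        data = PLMData(y=y, X=np.zeros((n, 1)), t=t)
        kern = ReproducingKernel(build_scaling_function("haar"), m)
        fit = fit_nonparametric(data, np.array([0.0]), kern, Partition.uniform(n), [0.3])
        assert fit.f_hat[0] == pytest.approx(y[4:8].mean(), abs=1e-12)

    def test_noiseless_sup_error_decreases_with_n(self, db2):
        sup_errors = []
        grid = np.linspace(0.1, 0.9, 81)
        for n in (64, 256, 1024):
            t = np.arange(1, n + 1) / n
            data = PLMData(y=np.sin(2 * np.pi * t), X=np.zeros((n, 1)), t=t)
            kern = ReproducingKernel(db2, choose_resolution(n))
            fit = fit_nonparametric(data, np.array([0.0]), kern, Partition.uniform(n), grid)
            sup_errors.append(np.abs(fit.f_hat - np.sin(2 * np.pi * grid)).max())
        assert sup_errors[0] > sup_errors[1] > sup_errors[2]

    def test_grid_outside_unit_interval_rejected(self, db2):
        n = 16
        t = np.arange(1, n + 1) / n
        data = PLMData(y=np.zeros(n), X=np.zeros((n, 1)), t=t)
        kern = ReproducingKernel(db2, 1)
        with pytest.raises(ValueError):
            fit_nonparametric(data, np.array([0.0]), kern, Partition.uniform(n), [1.5])


class TestTau2T:
    def test_iid_scalar_is_sum_of_squares(self, rng):
        w = rng.normal(size=20)
        assert tau2_t_plugin(w, 2.0) == pytest.approx(2.0 * (w @ w))
        assert tau2_t_plugin(np.zeros(20), 2.0) == 0.0

    def test_banded_covariance_matches_double_sum(self, rng):
        w = rng.normal(size=15)
        C = np.zeros((15, 15))
        np.fill_diagonal(C, 1.3)
        for i in range(14):
            C[i, i + 1] = C[i + 1, i] = -0.4
        oracle = sum(w[i] * C[i, j] * w[j] for i in range(15) for j in range(15))
        assert tau2_t_plugin(w, C) == pytest.approx(oracle, rel=1e-12)

    def test_negative_variance_rejected(self):
        w = np.array([1.0, -1.0])
        C = np.array([[0.0, 1.0], [1.0, 0.0]])  # w'Cw = -2
        with pytest.raises(ValueError):
            tau2_t_plugin(w, C)
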