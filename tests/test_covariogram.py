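"""Spectral densities, kernel evaluation, normalisation and truncation."""

import math

import numpy as np
import pytest

from manigp import (
    Circle,
    CovariogramSpec,
    Sphere,
    closed_form_matern_half,
    covariogram_eval,
    default_pd_xi,
    dyadic_circle_design,
    fibonacci_sphere_design,
    kernel_values,
    matern_half_circle_kernel,
    matern_spectral_density,
    normalizing_constant,
    pd_truncation_level,
    spectral_density,
    sq_exp_spectral_density,
    truncation_error_bound,
    truncation_required_level,
)
from manigp.covariogram import _cached_density


class TestSpecValidation:
    @pytest.mark.parametrize("bad", [dict(sigma2=0.0), dict(alpha=-1.0), dict(nu=0.0)])
    def test_nonpositive_parameters_rejected(self, circle, bad):
        kwargs = {**dict(sigma2=1.0, alpha=1.0, nu=0.5), **bad}
        with pytest.raises(ValueError):
            CovariogramSpec(manifold=circle, **kwargs)

    def test_dispatch_guards(self, circle):
        matern = CovariogramSpec(1.0, 1.0, 0.5, circle)
        se = CovariogramSpec(1.0, 1.0, math.inf, circle)
        with pytest.raises(ValueError):
            matern_spectral_density(se, 10)
        with pytest.raises(ValueError):
            sq_exp_spectral_density(matern, 10)


class TestMaternDensity:
    def test_circle_level_ratio(self, circle):
        # rho(0)/rho(1) = (alpha^2 + 4 pi^2)/alpha^2 = 1 + pi^2 at alpha = 2
        d = matern_spectral_density(CovariogramSpec(1.0, 2.0, 0.5, circle), 10)
        assert d.rho[0] / d.rho[1] == pytest.approx(1.0 + np.pi**2, rel=1e-12)

    def test_circle_half_matches_printed_form(self, circle_half_spec):
        # rho(n) = 2 sigma^2 alpha tanh(alpha/2) (alpha^2 + 4 pi^2 n^2)^{-1}
        d = matern_spectral_density(circle_half_spec, 50)
        n = np.arange(51)
        a = circle_half_spec.alpha
        expected = 2.0 * a * np.tanh(a / 2.0) / (a**2 + 4.0 * np.pi**2 * n**2)
        np.testing.assert_allclose(d.rho, expected, rtol=1e-10)

    @pytest.mark.parametrize(
    "spec",
        [
            CovariogramSpec(1.0, 2.0, 0.5, Circle()),
            CovariogramSpec(0.3, 1.0, 1.5, Circle()),
            CovariogramSpec(0.1, 1.0, 0.5, Sphere()),
            CovariogramSpec(2.0, 0.5, math.inf, Sphere()),
        ],
    )
    def test_diagonal_normalization(self, spec):
        # sum_l rho_l A_l(0) accounts for sigma^2 up to the reported tail
        d = spectral_density(spec, 300)
        diag = float(kernel_values(d, 0.0))
        assert diag + d.tail_bound == pytest.approx(spec.sigma2, rel=1e-9)
        # strictly positive and decreasing on the representable support
        # (squared-exponential weights underflow to zero at high levels)
        support = np.count_nonzero(d.rho > 0)
        assert support >= 1 and np.all(np.diff(d.rho[:support]) < 0)

    def test_truncated_normalization_is_exact_on_diagonal(self, sphere):
        spec = CovariogramSpec(0.7, 1.0, 2.5, sphere)
        d = spectral_density(spec, 200, normalization="truncated")
        assert float(kernel_values(d, 0.0)) == pytest.approx(0.7, rel=1e-14)

    def test_truncated_normalization_refuses_short_cache(self, circle):
        spec = CovariogramSpec(1.0, 2.0, 0.5, circle)
        with pytest.raises(ValueError, match="level"):
            spectral_density(spec, 30, normalization="truncated")

    def test_strictly_decreasing_in_eigenvalue(self, sphere):
        d = matern_spectral_density(CovariogramSpec(1.0, 3.0, 1.0, sphere), 100)
        assert np.all(np.diff(d.rho) < 0)


class TestSqExpDensity:
    def test_circle_ratio(self, circle):
        d = sq_exp_spectral_density(CovariogramSpec(1.0, 1.0, math.inf, circle), 5)
        assert d.rho[1] / d.rho[0] == pytest.approx(np.exp(-2.0 * np.pi**2), rel=1e-12)

    def test_tiny_alpha_degenerates_to_constant_field(self, circle):
        d = sq_exp_spectral_density(CovariogramSpec(1.0, 1e-4, math.inf, circle), 5)
        assert d.rho[0] == pytest.approx(1.0, rel=1e-12)
        assert np.all(d.rho[1:] == 0.0)

    def test_microergodic_identity_parameters(self, sphere):
        from manigp import microergodic_parameter

        spec = CovariogramSpec(0.4, 2.5, math.inf, sphere)
        assert microergodic_parameter(spec) == (0.4, 2.5)


class TestClosedFormOracle:
    def test_values(self, circle_half_spec):
        assert closed_form_matern_half(circle_half_spec, 0.3, 0.3) == pytest.approx(1.0)
        # antipodal separation: 1/cosh(1)
        assert closed_form_matern_half(circle_half_spec, 0.0, 0.5) == pytest.approx(
            1.0 / np.cosh(1.0), rel=1e-12
        )

    def test_symmetry_about_half(self):
        t = np.linspace(0.0, 1.0, 11)
        k = matern_half_circle_kernel(1.0, 2.0, t)
        np.testing.assert_allclose(k, k[::-1], rtol=1e-12)

    def test_wrong_manifold_or_smoothness_rejected(self, sphere, circle):
        with pytest.raises(ValueError):
            closed_form_matern_half(CovariogramSpec(1.0, 2.0, 0.5, sphere), 0.0, 0.1)
        with pytest.raises(ValueError):
            closed_form_matern_half(CovariogramSpec(1.0, 2.0, 1.5, circle), 0.0, 0.1)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0, 5.0])
    def test_spectral_sum_matches_closed_form(self, circle, alpha):
        spec = CovariogramSpec(1.0, alpha, 0.5, circle)
        x = np.linspace(0.0, 0.999, 100)
        y = np.zeros_like(x)
        np.testing.assert_allclose(
            covariogram_eval(spec, x, y, 500),
            closed_form_matern_half(spec, x, y),
            atol=1e-8,
        )

    def test_printed_partial_sum_examples(self, circle_half_spec):
        # antipodal and quarter separations at L = 200
        assert covariogram_eval(circle_half_spec, 0.0, 0.5, 200) == pytest.approx(
            1.0 / np.cosh(1.0), abs=1e-5
        )
        assert covariogram_eval(circle_half_spec, 0.0, 0.25, 200) == pytest.approx(
            np.cosh(0.5) / np.cosh(1.0), abs=1e-5
        )

    def test_bare_partial_sum_is_off_by_tail_bound(self, circle_half_spec):
        bare = covariogram_eval(circle_half_spec, 0.2, 0.2, 200, tail_completion=False)
        bound = truncation_error_bound(circle_half_spec, 200)
        assert abs(bare - 1.0) <= bound * (1.0 + 1e-9)
        assert abs(bare - 1.0) > 0.1 * bound  # the tail really is O(1/L)


class TestKernelProperties:
    def test_isotropy_circle_rotations(self, circle_half_spec, rng):
        x, y = 0.15, 0.6
        base = covariogram_eval(circle_half_spec, x, y, 100)
        for shift in rng.uniform(0, 1, 5):
            xs, ys = (x + shift) % 1.0, (y + shift) % 1.0
            assert covariogram_eval(circle_half_spec, xs, ys, 100) == pytest.approx(
                base, rel=1e-12
            )

    def test_isotropy_sphere_rotations(self, sphere, rng):
        spec = CovariogramSpec(0.1, 1.0, 1.0, sphere)
        x = np.array([1.0, 0.0, 0.0])
        y = np.array([0.0, 1.0, 0.0])
        base = covariogram_eval(spec, x, y, 60)
        for _ in range(5):
            Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            assert covariogram_eval(spec, Q @ x, Q @ y, 60) == pytest.approx(
                base, rel=1e-10
            )

    @pytest.mark.parametrize(
        "spec",
        [CovariogramSpec(0.7, 2.0, 0.5, Circle()), CovariogramSpec(0.1, 1.0, 1.5, Sphere())],
    )
    def test_bounded_by_sill(self, spec):
        d = spectral_density(spec, 300)
        t = np.linspace(0.0, 0.5 if spec.manifold.dim == 1 else np.pi, 200)
        assert np.all(np.abs(kernel_values(d, t)) <= spec.sigma2 + 1e-12)

    def test_smoothness_ordering_at_short_range(self, sphere):
        # larger nu concentrates spectral mass at low levels: higher
        # short-range correlation for fixed sigma^2, alpha
        t = np.linspace(0.01, 0.2, 20)
        curves = {
            nu: kernel_values(spectral_density(CovariogramSpec(1.0, 1.0, nu, sphere), 300), t)
            for nu in (0.5, 1.0, 2.0)
        }
        assert np.all(curves[1.0] > curves[0.5])
        assert np.all(curves[2.0] > curves[1.0])


class TestTruncationControl:
    def test_bound_nonincreasing_and_rate(self, sphere):
        spec = CovariogramSpec(0.1, 1.0, 0.5, sphere)
        Ls = np.array([50, 100, 200, 400, 800, 1600])
        bounds = np.array([truncation_error_bound(spec, L) for L in Ls])
        assert np.all(np.diff(bounds) < 0)
        slope = np.polyfit(np.log(Ls), np.log(bounds), 1)[0]
        assert slope == pytest.approx(-2.0 * spec.nu, rel=0.1)

    def test_bound_argument_validation(self, sphere):
        spec = CovariogramSpec(0.1, 1.0, 0.5, sphere)
        with pytest.raises(ValueError):
            truncation_error_bound(spec, -1)
        with pytest.raises(ValueError):
            truncation_required_level(spec, 0.0)

    def test_required_level_inverts_bound(self, sphere):
        spec = CovariogramSpec(0.1, 1.0, 1.0, sphere)
        L = truncation_required_level(spec, 1e-6)
        assert truncation_error_bound(spec, L) <= 1e-6
        assert truncation_error_bound(spec, L - 1) > 1e-6

    def test_pd_level_monotone_in_n_and_nu(self, sphere):
        xi = 1e-3
        d30, d60 = fibonacci_sphere_design(30), fibonacci_sphere_design(60)
        spec_half = CovariogramSpec(0.1, 1.0, 0.5, sphere)
        spec_two = CovariogramSpec(0.1, 1.0, 2.0, sphere)
        assert pd_truncation_level(spec_half, d60, xi) >= pd_truncation_level(
            spec_half, d30, xi
        )
        assert pd_truncation_level(spec_two, d30, xi) <= pd_truncation_level(
            spec_half, d30, xi
        )
        with pytest.raises(ValueError):
            pd_truncation_level(spec_half, d30, 0.0)

    @pytest.mark.parametrize("n", [12, 24, 40])
    def test_certified_level_gives_positive_definite_matrix(self, sphere, n):
        spec = CovariogramSpec(0.1, 1.0, 1.0, sphere)
        design = fibonacci_sphere_design(n)
        xi = default_pd_xi(spec, design)
        L = pd_truncation_level(spec, design, xi)
        K = kernel_values(_cached_density(spec, L), design.distances)
        assert np.linalg.eigvalsh(K)[0] > 0.0

    def test_dyadic_design_covariance_pd_at_certified_level(self, circle):
        spec = CovariogramSpec(1.0, 2.0, 1.5, circle)
        design = dyadic_circle_design(4)
        xi = default_pd_xi(spec, design)
        L = pd_truncation_level(spec, design, xi)
        K = kernel_values(_cached_density(spec, L), design.distances)
        assert np.linalg.eigvalsh(K)[0] > 0.0


def test_normalizer_closed_form_cross_check(circle):
    # C = coth(alpha/2) / (2 alpha) on the unit-circumference circle, nu=1/2
    for alpha in (0.5, 1.0, 2.0, 5.0):
        spec = CovariogramSpec(1.0, alpha, 0.5, circle)
        expected = 1.0 / (np.tanh(alpha / 2.0) * 2.0 * alpha)
        assert normalizing_constant(spec) == pytest.approx(expected, rel=1e-10)
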