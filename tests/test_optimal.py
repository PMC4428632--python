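"""Optimal feedback construction and its internal consistency."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import qscensus as qs
from qscensus.channel import _SQRT_2PIE
from qscensus.dynamics import ChannelStats


class TestClosedFormIntegrals:
    def test_tf_inverse_fano_integral(self, params):
        model = qs.RegulationModel.for_channel(params, "tf")
        exact = qs.fano_inverse_integral(model, 100.0, 600.0)
        assert exact == pytest.approx(500.0 * params.v / 21.0, rel=1e-14)

    def test_srna_inverse_fano_integral_vs_quadrature(self, params):
        model = qs.RegulationModel.for_channel(params, "srna")
        exact = qs.fano_inverse_integral(model, 100.0, 600.0)
        num, _ = quad(lambda m: 1.0 / model.fano(m), 100.0, 600.0)
        assert exact == pytest.approx(num, rel=1e-10)

    def test_unit_budget_reduces_log_factor(self, params):
        p1 = params.with_(f_int_minus=1.0, f_int_plus=1.0)
        model = qs.RegulationModel.for_channel(p1, "tf", f_int_plus=1.0)
        J = qs.fano_inverse_integral(model, p1.m_minus, p1.m_plus)
        expected = 0.5 * math.log2(
            math.log(p1.m_plus / p1.m_minus) * J / (2 * math.pi * math.e)
        )
        assert qs.optimal_smallnoise_mi(p1, model) == pytest.approx(expected)


class TestOptimalInternalFeedback:
    def test_boundary_values_pinned(self, params, srna_optimal, tf_optimal):
        for sol in (srna_optimal, tf_optimal):
            assert sol.f_int_star(params.m_minus) == pytest.approx(2.0)
            assert sol.f_int_star(params.m_plus) == pytest.approx(0.5)

    def test_capacity_of_constructed_sigma_reproduces_closed_form(
        self, params
    ):
        """Plugging Sigma* back into the capacity integral must return the
        closed-form optimum to 1e-6 bits, for both regulation models."""
        for kind in ("tf", "srna"):
            model = qs.RegulationModel.for_channel(params, kind)
            internal = qs.optimal_internal_feedback(params, model)
            Z, _ = quad(
                lambda m: 1.0 / (_SQRT_2PIE * internal.sigma_star(m)),
                params.m_minus, params.m_plus,
            )
            assert math.log2(Z) == pytest.approx(
                qs.optimal_smallnoise_mi(params, model), abs=1e-6
            )

    def test_feedback_direction_differs_between_models(self, params,
                                                       tf_optimal,
                                                       srna_optimal):
        # TF: self-induction at low abundance; sRNA: repression throughout
        low = params.m_minus * 1.05
        assert tf_optimal.f_int_star.derivative(low) > 0
        assert srna_optimal.f_int_star.derivative(low) < 0
        m = np.linspace(params.m_minus, params.m_plus, 64)
        assert np.all(srna_optimal.f_int_star.derivative(m) < 0)

    def test_optimal_fano_is_reduced_where_feedback_represses(
        self, params, srna_optimal
    ):
        m = np.linspace(params.m_minus, params.m_plus, 64)
        F1 = srna_optimal.model.fano(m)
        Fs = srna_optimal.stats.F_star(m)
        assert np.all(Fs < F1)

    def test_swapping_boundary_budget_loses_information(self, params):
        swapped = params.with_(f_int_minus=0.5, f_int_plus=2.0)
        for kind in ("tf", "srna"):
            model = qs.RegulationModel.for_channel(params, kind)
            model_s = qs.RegulationModel.for_channel(
                swapped, kind, f_int_plus=params.f_int_plus
            )
            assert qs.optimal_smallnoise_mi(swapped, model_s) < \
                qs.optimal_smallnoise_mi(params, model)


class TestOptimalMapping:
    def test_constant_noise_reduces_to_histogram_equalization(
        self, params, profile, tf_optimal
    ):
        eq = qs.equalization_mapping(profile, params)
        rho = np.geomspace(params.rho_minus, params.rho_plus, 33)
        assert np.allclose(tf_optimal.mapping.m_bar(rho), eq(rho), rtol=1e-12)

    def test_boundary_pinning(self, params, srna_optimal):
        assert srna_optimal.mapping.m_bar(params.rho_minus) == pytest.approx(
            params.m_minus
        )
        assert srna_optimal.mapping.m_bar(params.rho_plus) == pytest.approx(
            params.m_plus
        )

    def test_tf_time_course_is_linear(self, params, tf_optimal):
        t = np.linspace(0.0, params.T, 65)
        m_t = tf_optimal.mapping.time_course(t)
        assert np.allclose(np.diff(m_t, 2), 0.0, atol=1e-8 * params.m_plus)

    def test_output_distribution_inverse_to_noise(self, params, srna_optimal):
        # q(m) = p(rho)/m_bar' must be proportional to 1/Sigma*(m)
        rho = np.geomspace(params.rho_minus * 2, params.rho_plus / 2, 17)
        profile = srna_optimal.profile
        m = np.asarray(srna_optimal.mapping.m_bar(rho), float)
        q = np.asarray(profile.pdf(rho), float) / np.asarray(
            srna_optimal.mapping.m_bar_prime(rho), float
        )
        prod = q * np.asarray(srna_optimal.internal.sigma_star(m), float)
        assert np.allclose(prod, prod[0], rtol=1e-8)


class TestOptimalAIMapping:
    def test_boundary_conditions(self, params, srna_optimal):
        assert srna_optimal.a_bar_star(params.rho_minus) == pytest.approx(
            params.a_minus, rel=1e-5
        )
        assert srna_optimal.a_bar_star(params.rho_plus) == pytest.approx(
            params.a_plus, rel=1e-5
        )

    def test_self_consistency_plug_back(self, params, srna_optimal):
        rho = np.geomspace(params.rho_minus, params.rho_plus, 33)
        m = np.asarray(srna_optimal.mapping.m_bar(rho), float)
        a = np.asarray(srna_optimal.a_bar_star(rho), float)
        recon = params.tau_m * np.asarray(srna_optimal.rate(a), float) * \
            np.asarray(srna_optimal.f_int_star(m), float)
        assert np.allclose(recon, m, rtol=1e-8)

    def test_ai_course_concentrates_near_K(self, params, srna_optimal):
        t = np.linspace(0.0, params.T, 2001)
        a = np.asarray(srna_optimal.a_bar_star(srna_optimal.profile.density(t)),
                       float)
        frac = np.mean((a > params.K / 10) & (a < 10 * params.K))
        assert frac > 0.5


class TestOptimalExternalFeedback:
    def test_low_density_normalization(self, params, srna_optimal):
        f_minus = params.a_minus / (params.tau_a * params.rho_minus)
        assert srna_optimal.f_ext_star(params.m_minus) / f_minus == \
            pytest.approx(1.0, rel=1e-6)

    def test_round_trip_through_fixed_points(self, params, srna_optimal):
        """Feeding (f_ext*, f_int*) back through the joint fixed-point solver
        recovers the optimal mean mapping."""
        for rho in np.geomspace(params.rho_minus * 2, params.rho_plus / 2, 7):
            _, m_bar = qs.solve_fixed_point(
                params, srna_optimal.rate, srna_optimal.feedbacks, rho
            )
            assert m_bar == pytest.approx(
                float(srna_optimal.mapping.m_bar(rho)), rel=1e-6
            )


class TestNoFeedbackBaseline:
    def test_linear_ai_course(self, params, tf_baseline):
        rho = np.geomspace(params.rho_minus, params.rho_plus, 9)
        a = np.asarray(tf_baseline.maps.a_bar(rho), float)
        assert np.allclose(a, params.a_minus * rho / params.rho_minus)
        assert a[0] == pytest.approx(params.a_minus)
        assert a[-1] == pytest.approx(params.a_minus * 1e4)

    def test_fano_equals_bare_function(self, params, srna_baseline):
        m = np.linspace(*srna_baseline.maps.m_range, 17)
        assert np.allclose(srna_baseline.stats.F_star(m),
                           srna_baseline.model.fano(m))

    def test_baseline_spans_fixed_mp_range(self, params, srna_baseline):
        lo, hi = srna_baseline.maps.m_range
        assert lo == pytest.approx(params.m_minus, rel=1e-10)
        assert hi == pytest.approx(params.m_plus, rel=2e-4)

    def test_baseline_srna_model_has_no_self_inhibition_headroom(
        self, params, srna_baseline
    ):
        assert srna_baseline.model.m_infty == pytest.approx(params.m_plus)


class TestInformationOrdering:
    def test_optimal_feedback_beats_baseline(self, params):
        for kind in ("tf", "srna"):
            base = qs.no_feedback_baseline(params, kind)
            opt = qs.optimal_solution(params, kind)
            mi_base = qs.numerical_mi(
                qs.build_channel(base.maps, base.stats, n_rho=256, n_m=256)
            ).value
            mi_opt = qs.numerical_mi(
                qs.build_channel(opt.maps, opt.stats, n_rho=256, n_m=256)
            ).value
            assert mi_opt > mi_base

    @pytest.mark.parametrize("b", [1.0, 5.0, 20.0])
    def test_small_noise_mi_lower_bounds_numerical_mi(self, params, profile, b):
        """The quadrature approximation neglects the output-noise entropy and
        must lower-bound the exact (untruncated) channel MI."""
        p_b = params.with_(b=b)
        for kind in ("tf", "srna"):
            for sol in (qs.no_feedback_baseline(p_b, kind),
                        qs.optimal_solution(p_b, kind)):
                approx = qs.small_noise_mi(profile, sol.maps, sol.stats).value
                exact = qs.numerical_mi(
                    qs.build_channel(sol.maps, sol.stats, n_rho=256, n_m=512,
                                     truncation="none")
                ).value
                assert approx <= exact + 1e-3

    def test_numerical_mi_approaches_capacity_as_noise_vanishes(
        self, params, tf_optimal
    ):
        """Scaling the noise amplitude toward zero closes the gap between the
        exact channel MI under the capacity input and the small-noise
        capacity."""
        maps, stats = tf_optimal.maps, tf_optimal.stats
        gaps = []
        for eps in (1.0, 0.3, 0.03):
            scaled = ChannelStats(
                sigma_sq=lambda r, e=eps: e**2 * np.asarray(
                    stats.sigma_sq(r), float),
                delta_rho=lambda r, e=eps: e * np.asarray(
                    stats.delta_rho(r), float),
                F_star=stats.F_star,
                tau_star=stats.tau_star,
                sigma_m=stats.sigma_m,
            )
            cap = qs.small_noise_capacity(maps, scaled).value
            mi = qs.numerical_mi(
                qs.build_channel(maps, scaled, n_rho=512, n_m=1024,
                                 truncation="none")
            ).value
            gaps.append(mi - cap)
        assert gaps[0] > gaps[1] > gaps[2] > -1e-3
        assert abs(gaps[-1]) < 0.02
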