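"""Discretized Gaussian channel, mutual information, and capacity."""

import math

import numpy as np
import pytest

import qscensus as qs
from qscensus.channel import DiscretizedChannel, _SQRT_2PIE
from qscensus.dynamics import ChannelStats, MeanFieldMaps, TabulatedGrowthProfile


def _uniform_noise_setup(rho1=1.0, rho2=11.0, m_lo=100.0, m_hi=600.0, sigma=17.0):
    """Linear mean mapping with constant noise over a uniform input."""
    t = np.linspace(0.0, 1.0, 2001)
    profile = TabulatedGrowthProfile(t, rho1 + (rho2 - rho1) * t)
    slope = (m_hi - m_lo) / (rho2 - rho1)
    maps = MeanFieldMaps(
        rho_range=(rho1, rho2),
        a_bar=lambda r: np.asarray(r, float),
        m_bar=lambda r: m_lo + slope * (np.asarray(r, float) - rho1),
        a_bar_prime=lambda r: np.ones_like(np.asarray(r, float)),
        m_bar_prime=lambda r: np.full_like(np.asarray(r, float), slope),
    )
    stats = ChannelStats(
        sigma_sq=lambda r: np.full_like(np.asarray(r, float), sigma**2),
        delta_rho=lambda r: np.full_like(np.asarray(r, float), sigma / slope),
        F_star=lambda m: np.ones_like(np.asarray(m, float)),
        tau_star=lambda m: np.ones_like(np.asarray(m, float)),
        sigma_m=lambda m: np.full_like(np.asarray(m, float), sigma),
    )
    return profile, maps, stats, slope


class TestChannelConstruction:
    def test_rows_are_normalized(self, srna_optimal):
        for trunc in ("hard", "none"):
            ch = qs.build_channel(srna_optimal.maps, srna_optimal.stats,
                                  n_rho=128, n_m=128, truncation=trunc)
            ch.validate()

    def test_row_moments_match_gaussian(self):
        _, maps, stats, _ = _uniform_noise_setup()
        ch = qs.build_channel(maps, stats, n_rho=64, n_m=512, truncation="none")
        centers = ch.m_centers
        i = 32  # interior row
        mu = float(ch.P[i] @ centers)
        var = float(ch.P[i] @ (centers - mu) ** 2)
        assert mu == pytest.approx(maps.m_bar(ch.rho_grid[i]), rel=1e-6)
        assert var == pytest.approx(17.0**2, rel=1e-3)

    def test_zero_noise_rejected(self):
        _, maps, stats, _ = _uniform_noise_setup(sigma=17.0)
        bad = ChannelStats(
            sigma_sq=lambda r: np.zeros_like(np.asarray(r, float)),
            delta_rho=stats.delta_rho, F_star=stats.F_star,
            tau_star=stats.tau_star, sigma_m=stats.sigma_m,
        )
        with pytest.raises(ValueError, match="deterministic"):
            qs.build_channel(maps, bad, n_rho=16, n_m=16)


class TestNumericalMI:
    def test_input_independent_channel_carries_nothing(self):
        P = np.tile(np.full(8, 1.0 / 8), (5, 1))
        ch = DiscretizedChannel(np.arange(1.0, 6.0), np.arange(9.0), P, "hard")
        assert qs.numerical_mi(ch).value == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_permutation_channel(self):
        n = 8
        ch = DiscretizedChannel(
            np.arange(1.0, n + 1), np.arange(n + 1.0),
            np.eye(n)[::-1], "hard",
        )
        assert qs.numerical_mi(ch).value == pytest.approx(math.log2(n))

    def test_input_validation(self, srna_optimal):
        ch = qs.build_channel(srna_optimal.maps, srna_optimal.stats,
                              n_rho=32, n_m=32)
        with pytest.raises(ValueError, match="grid"):
            qs.numerical_mi(ch, np.full(16, 1 / 16))
        with pytest.raises(ValueError, match="sum"):
            qs.numerical_mi(ch, np.full(32, 1 / 16))

    def test_invariance_under_input_relabeling(self, srna_optimal):
        ch = qs.build_channel(srna_optimal.maps, srna_optimal.stats,
                              n_rho=128, n_m=128)
        relabeled = DiscretizedChannel(
            ch.rho_grid**2, ch.m_edges, ch.P, ch.truncation
        )
        a = qs.numerical_mi(ch).value
        b = qs.numerical_mi(relabeled).value
        assert abs(a - b) < 1e-12


class TestBlahutArimoto:
    def test_binary_noiseless_channel(self):
        ch = DiscretizedChannel(
            np.array([1.0, 2.0]), np.array([0.0, 1.0, 2.0]), np.eye(2), "hard"
        )
        res = qs.blahut_arimoto(ch, tol=1e-9)
        assert res.value == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(res.diagnostics["p_star"], 0.5)

    def test_capacity_dominates_reference_input(self, srna_optimal):
        ch = qs.build_channel(srna_optimal.maps, srna_optimal.stats,
                              n_rho=128, n_m=128)
        cap = qs.blahut_arimoto(ch, tol=1e-4, max_iter=50_000)
        assert cap.diagnostics["upper_bits"] >= qs.numerical_mi(ch).value - 1e-9

    def test_iteration_budget_error_carries_bracket(self, srna_optimal):
        ch = qs.build_channel(srna_optimal.maps, srna_optimal.stats,
                              n_rho=64, n_m=64)
        with pytest.raises(qs.ConvergenceError) as exc:
            qs.blahut_arimoto(ch, tol=1e-9, max_iter=3)
        assert exc.value.upper >= exc.value.lower


class TestSmallNoise:
    def test_constant_resolution_closed_form(self):
        profile, maps, stats, slope = _uniform_noise_setup()
        res = qs.small_noise_mi(profile, maps, stats)
        expected = math.log2((11.0 - 1.0) / (_SQRT_2PIE * 17.0 / slope))
        assert res.value == pytest.approx(expected, abs=1e-6)
        assert res.approximate

    def test_doubling_noise_costs_one_bit(self):
        profile, maps, stats, _ = _uniform_noise_setup(sigma=17.0)
        profile2, maps2, stats2, _ = _uniform_noise_setup(sigma=34.0)
        a = qs.small_noise_mi(profile, maps, stats).value
        b = qs.small_noise_mi(profile2, maps2, stats2).value
        assert a - b == pytest.approx(1.0, abs=1e-8)

    def test_reparametrization_invariance(self, params, srna_baseline, profile):
        """The small-noise MI is a change-of-variables invariant: encoding
        rho through x = rho^2 leaves it unchanged."""
        base = qs.small_noise_mi(profile, srna_baseline.maps,
                                 srna_baseline.stats).value
        t = np.linspace(0.0, params.T, 4001)
        profile_x = TabulatedGrowthProfile(t, profile.density(t) ** 2)
        maps, stats = srna_baseline.maps, srna_baseline.stats
        maps_x = MeanFieldMaps(
            rho_range=(params.rho_minus**2, params.rho_plus**2),
            a_bar=lambda x: maps.a_bar(np.sqrt(x)),
            m_bar=lambda x: maps.m_bar(np.sqrt(x)),
            a_bar_prime=lambda x: maps.a_bar_prime(np.sqrt(x))
            / (2 * np.sqrt(x)),
            m_bar_prime=lambda x: maps.m_bar_prime(np.sqrt(x))
            / (2 * np.sqrt(x)),
        )
        stats_x = ChannelStats(
            sigma_sq=lambda x: stats.sigma_sq(np.sqrt(x)),
            delta_rho=lambda x: np.sqrt(stats.sigma_sq(np.sqrt(x)))
            / maps_x.m_bar_prime(x),
            F_star=stats.F_star,
            tau_star=stats.tau_star,
            sigma_m=stats.sigma_m,
        )
        trans = qs.small_noise_mi(profile_x, maps_x, stats_x).value
        assert trans == pytest.approx(base, abs=2e-3)


class TestSmallNoiseCapacity:
    def test_capacity_upper_bounds_mi_and_matches_at_capacity_input(
        self, profile, srna_baseline, srna_optimal
    ):
        for sol in (srna_baseline, srna_optimal):
            cap = qs.small_noise_capacity(sol.maps, sol.stats).value
            mi = qs.small_noise_mi(profile, sol.maps, sol.stats).value
            assert cap >= mi - 1e-9
        # the optimal construction makes 1/rho the capacity input
        cap = qs.small_noise_capacity(srna_optimal.maps, srna_optimal.stats)
        mi = qs.small_noise_mi(profile, srna_optimal.maps, srna_optimal.stats)
        assert cap.value == pytest.approx(mi.value, abs=1e-6)

    def test_density_and_mp_domain_forms_agree(self, srna_optimal):
        cap = qs.small_noise_capacity(srna_optimal.maps, srna_optimal.stats)
        assert cap.diagnostics["m_domain_bits"] == pytest.approx(
            cap.value, abs=1e-8
        )


class TestDistinguishableStates:
    @pytest.mark.parametrize(
        "bits,expected",
        [(1.0, (2, 2)), (1.4, (2, 3)), (2.1, (4, 5)), (2.0, (4, 4)),
         (0.0, (1, 1))],
    )
    def test_state_counts(self, bits, expected):
        assert qs.distinguishable_states(bits) == expected

    def test_negative_information_rejected(self):
        with pytest.raises(ValueError):
            qs.distinguishable_states(-0.1)
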