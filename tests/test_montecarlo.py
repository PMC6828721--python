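import math

import numpy as np
import pytest

from aquarisk.distributions import DistributionSpec, fit_lognormal_from_summary
from aquarisk.errors import DomainError, RouteError
from aquarisk.exposure import ExposureProfile, default_toxicity
from aquarisk.montecarlo import (
    RiskDistribution,
    analytic_exceedance_normal,
    exceedance_fraction,
    percentile_summary,
    simulate_risk,
)

ADULT = ExposureProfile("adult", ir_w=2.0, ef_r=350.0, ed=30.0, bw=70.0)
TOX = default_toxicity()


def _point(v):
    return DistributionSpec("point", (v,))


class TestSimulateRisk:
    def test_degenerate_inputs_reproduce_deterministic_value(self):
        dist = simulate_risk(_point(70.0), ADULT, TOX, "Pb", n=50, seed=0)
        # HQ with AT = ED×365: 70×2×350/(70×365×1.4)
        expected = 70.0 * 2.0 * 350.0 * 30.0 / (70.0 * 30.0 * 365.0 * 1.4)
        assert np.allclose(dist.draws, expected, rtol=1e-12)

    def test_same_seed_identical_draws(self):
        conc = fit_lognormal_from_summary(56.0, 25.0)
        a = simulate_risk(conc, ADULT, TOX, "Pb", n=10_000, seed=42)
        b = simulate_risk(conc, ADULT, TOX, "Pb", n=10_000, seed=42)
        assert np.array_equal(a.draws, b.draws)
        assert not np.array_equal(
            a.draws, simulate_risk(conc, ADULT, TOX, "Pb", n=10_000, seed=43).draws
        )

    def test_mean_matches_linear_pushforward_of_concentration_mean(self):
        m, sd = 56.0, 25.0
        conc = fit_lognormal_from_summary(m, sd)
        dist = simulate_risk(conc, ADULT, TOX, "Pb", n=100_000, seed=9)
        scale = 2.0 * 350.0 / (70.0 * 365.0 * 1.4)  # HQ per unit concentration
        se = sd * scale / math.sqrt(dist.n)
        assert abs(dist.draws.mean() - m * scale) < 3 * se

    def test_stochastic_exposure_factor_is_sampled(self):
        bw = DistributionSpec("normal", (70.0, 7.0), truncation=(40.0, 120.0))
        p = ExposureProfile("adult", ir_w=2.0, ef_r=350.0, ed=30.0, bw=bw)
        dist = simulate_risk(_point(70.0), p, TOX, "Pb", n=5000, seed=1)
        assert dist.draws.std() > 0
        assert dist.draws.mean() == pytest.approx(
            simulate_risk(_point(70.0), ADULT, TOX, "Pb", n=10, seed=1).draws[0],
            rel=0.05,
        )

    def test_cancer_risk_for_dermal_route_rejected(self):
        with pytest.raises(RouteError):
            simulate_risk(_point(70.0), ADULT, TOX, "Ni", route="dermal",
                          endpoint="LTCR", n=10, seed=0)

    def test_percentiles_scale_linearly_with_concentration(self):
        k = 3.7
        conc = fit_lognormal_from_summary(56.0, 25.0)
        mu, sigma = conc.params
        scaled = DistributionSpec("lognormal", (mu + math.log(k), sigma))
        a = simulate_risk(conc, ADULT, TOX, "Pb", n=20_000, seed=5).summary()
        b = simulate_risk(scaled, ADULT, TOX, "Pb", n=20_000, seed=5).summary()
        for level, q in a.percentiles.items():
            assert b[level] == pytest.approx(k * q, rel=1e-12)


class TestPercentileSummary:
    def test_point_mass(self):
        s = percentile_summary(np.full(100, 3.25))
        assert all(v == 3.25 for v in s.percentiles.values())
        assert s.mean == 3.25 and s.sd == 0.0

    @pytest.mark.parametrize(
        "mean,sd,level,printed",
        [(1.108, 0.504, 90.0, 1.753), (1.864, 0.8389, 95.0, 3.240)],
    )
    def test_simulated_upper_percentiles_match_published_rows(
        self, mean, sd, level, printed
    ):
        spec = DistributionSpec("normal", (mean, sd))
        draws = spec.sample(100_000, np.random.default_rng(17))
        s = percentile_summary(draws)
        assert s[level] == pytest.approx(printed, rel=0.01)

    def test_quantiles_monotone_in_level(self):
        rng = np.random.default_rng(4)
        draws = rng.lognormal(0, 1.5, 997)
        s = percentile_summary(draws, levels=(1, 5, 25, 50, 75, 90, 99, 99.9))
        qs = [s[l] for l in (1, 5, 25, 50, 75, 90, 99, 99.9)]
        assert all(a <= b for a, b in zip(qs, qs[1:]))
        assert min(draws) <= s[50] <= max(draws)

    def test_levels_outside_open_interval_rejected(self):
        with pytest.raises(DomainError):
            percentile_summary(np.arange(10.0), levels=(0.0,))
        with pytest.raises(DomainError):
            percentile_summary(np.arange(10.0), levels=(100.0,))


class TestExceedance:
    def test_threshold_below_every_draw(self):
        assert exceedance_fraction(np.array([2.0, 3.0]), 1.0) == 100.0

    def test_matches_analytic_normal_within_binomial_error(self):
        mean, sd, thr, n = 1.108, 0.504, 1.0, 100_000
        spec = DistributionSpec("normal", (mean, sd))
        draws = spec.sample(n, np.random.default_rng(23))
        p = analytic_exceedance_normal(mean, sd, thr)
        tol = 3 * math.sqrt(p * (1 - p) / n) * 100
        assert exceedance_fraction(draws, thr) == pytest.approx(100 * p, abs=tol)
        assert 100 * p == pytest.approx(58.40, abs=0.5)

    def test_error_shrinks_like_inverse_sqrt_n(self):
        """Average |MC − analytic| error follows the 1/√n law (log–log slope)."""
        mean, sd, thr = 1.108, 0.504, 1.0
        spec = DistributionSpec("normal", (mean, sd))
        p = analytic_exceedance_normal(mean, sd, thr)
        sizes = (1000, 10_000, 100_000)
        errs = []
        for n in sizes:
            reps = [
                abs(exceedance_fraction(
                    spec.sample(n, np.random.default_rng(1000 + r)), thr
                ) / 100 - p)
                for r in range(30)
            ]
            errs.append(np.mean(reps))
        slope = np.polyfit(np.log(sizes), np.log(errs), 1)[0]
        assert -0.65 < slope < -0.35


class TestAnalyticOracle:
    def test_threshold_at_mean_is_half(self):
        assert analytic_exceedance_normal(3.0, 1.2, 3.0) == pytest.approx(0.5)

    def test_published_borehole_row(self):
        assert analytic_exceedance_normal(1.108, 0.504, 1.0) == pytest.approx(
            0.5848, abs=5e-4)

    def test_published_well_child_row(self):
        p = analytic_exceedance_normal(7.606, 4.200, 1.0)
        assert p == pytest.approx(0.9421, abs=5e-4)
        assert abs(100 * p - 94.07) < 0.5

    def test_degenerate_sd_rejected(self):
        with pytest.raises(DomainError):
            analytic_exceedance_normal(1.0, 0.0, 0.5)


def test_risk_distribution_invariants():
    with pytest.raises(DomainError):
        RiskDistribution(np.array([]))
    with pytest.raises(DomainError):
        RiskDistribution(np.array([1.0, -0.1]))
    with pytest.raises(DomainError):
        RiskDistribution(np.array([np.inf]))
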