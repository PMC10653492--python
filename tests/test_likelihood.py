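"""Poisson life-table likelihood, penalty, prior and expected log-likelihood."""

import numpy as np
import pytest

from ggfrailty import (
    LifeTable,
    PenaltyConfig,
    ThetaGG,
    expected_loglik,
    penalized_loglik,
    penalty,
    poisson_loglik,
    prior_summary,
    sample_lifespans,
)
from ggfrailty.models import gg_marginal_density, gg_marginal_hazard


def random_table(rng, n_ages=5):
    return LifeTable(
        D=rng.integers(0, 30, n_ages).astype(float),
        E=rng.uniform(5, 500, n_ages),
    )


class TestLifeTable:
    def test_validation(self):
        with pytest.raises(ValueError):
            LifeTable(D=[1.0], E=[2.0])  # too short
        with pytest.raises(ValueError):
            LifeTable(D=[1.0, 2.0], E=[2.0])  # length mismatch
        with pytest.raises(ValueError):
            LifeTable(D=[1.0, -2.0], E=[2.0, 2.0])
        with pytest.raises(ValueError):
            LifeTable(D=[1.0, 2.0], E=[2.0, 0.0])  # deaths without exposure

    def test_observed_rates(self):
        lt = LifeTable(D=[2.0, 0.0], E=[4.0, 0.0])
        m = lt.observed_rates
        assert m[0] == 0.5 and np.isnan(m[1])


class TestPoissonLoglik:
    def test_single_effective_interval_closed_form(self):
        # at x=0 the marginal hazard equals a, so the only contributing term
        # is 2 ln 0.2 - 10*0.2; the second age has no exposure
        lt = LifeTable(D=[2.0, 0.0], E=[10.0, 0.0])
        val = poisson_loglik(ThetaGG(a=0.2, b=0.05, sigma2=0.0), lt)
        assert val == pytest.approx(2 * np.log(0.2) - 10 * 0.2, abs=1e-10)
        assert val == pytest.approx(-5.21888, abs=1e-5)

    def test_all_zero_deaths(self):
        th = ThetaGG(0.01, 0.1, 0.3)
        lt = LifeTable(D=[0.0, 0.0, 0.0], E=[10.0, 20.0, 5.0])
        mu = gg_marginal_hazard(lt.ages, th)
        assert poisson_loglik(th, lt) == pytest.approx(-np.sum(lt.E * mu), rel=1e-12)

    def test_term_by_term_oracle(self):
        rng = np.random.default_rng(42)
        th = ThetaGG(0.002, 0.11, 0.4)
        lt = random_table(rng)
        expected = 0.0
        for x in range(len(lt)):
            mu = gg_marginal_hazard(float(x), th)
            expected += lt.D[x] * np.log(mu) - lt.E[x] * mu
        assert poisson_loglik(th, lt) == pytest.approx(expected, rel=1e-12)

    def test_midpoint_offset(self):
        rng = np.random.default_rng(3)
        th = ThetaGG(0.002, 0.11, 0.1)
        lt = random_table(rng)
        left = poisson_loglik(th, lt, age_offset=0.0)
        mid = poisson_loglik(th, lt, age_offset=0.5)
        assert left != mid

    def test_more_exposure_decreases_loglik(self):
        rng = np.random.default_rng(7)
        th = ThetaGG(0.001, 0.1, 0.2)
        lt = random_table(rng)
        bigger = LifeTable(D=lt.D, E=lt.E + 10.0)
        assert poisson_loglik(th, bigger) < poisson_loglik(th, lt)


class TestPenalty:
    def test_values(self):
        cfg = PenaltyConfig(lam=0.5)
        assert penalty(1.0, cfg) == pytest.approx(-0.5)
        assert penalty(2.0, PenaltyConfig(lam=0.0)) == 0.0
        assert penalty(0.5, cfg) > penalty(1.0, cfg)

    def test_diverges_at_zero(self):
        cfg = PenaltyConfig()
        assert penalty(1e-300, cfg) > 300
        with pytest.raises(ValueError):
            penalty(0.0, cfg)

    def test_penalized_is_sum(self):
        rng = np.random.default_rng(11)
        th = ThetaGG(0.001, 0.1, 0.7)
        lt = random_table(rng)
        cfg = PenaltyConfig(lam=0.5)
        assert penalized_loglik(th, lt, cfg) == poisson_loglik(th, lt) + penalty(
            th.sigma2, cfg
        )
        # structure of the lambda = 1/2 objective
        diff = penalized_loglik(th, lt, cfg) - poisson_loglik(th, lt)
        assert diff == pytest.approx(-0.5 * (np.log(th.sigma2) + th.sigma2), rel=1e-12)

    def test_lambda_zero_is_plain_likelihood_bitwise(self):
        rng = np.random.default_rng(13)
        th = ThetaGG(0.003, 0.09, 0.25)
        lt = random_table(rng)
        cfg = PenaltyConfig(lam=0.0)
        assert penalized_loglik(th, lt, cfg) == poisson_loglik(th, lt)

    def test_penalized_grid_max_at_smallest_sigma2_for_gompertz_data(
        self, gompertz_table
    ):
        # without deceleration in the data the penalized objective keeps
        # growing as sigma2 shrinks: its grid maximum sits at the left edge
        cfg = PenaltyConfig()
        grid = np.logspace(-8, 0, 30)
        vals = [
            penalized_loglik(ThetaGG(0.0001, 0.1, s2), gompertz_table, cfg)
            for s2 in grid
        ]
        assert int(np.argmax(vals)) == 0


class TestPriorSummary:
    def test_half_lambda_prior(self):
        ps = prior_summary(0.5)
        assert ps["shape"] == 0.5 and ps["rate"] == 0.5
        assert ps["mean"] == pytest.approx(1.0)
        assert ps["median"] == pytest.approx(0.4549, abs=1e-4)
        assert ps["mass_01"] == pytest.approx(0.6827, abs=1e-4)
        assert ps["mode"] == 0.0

    def test_rejects_out_of_range(self):
        for lam in (0.0, 1.0, -0.2, 2.0):
            with pytest.raises(ValueError):
                prior_summary(lam)


class TestExpectedLoglik:
    TRUE = ThetaGG(0.0001, 0.1, 0.0)

    def test_information_inequality(self):
        # the expected log-likelihood over a theta grid is maximised at the
        # truth (with sigma2 at its numerical floor)
        best = expected_loglik(ThetaGG(0.0001, 0.1, 1e-10), self.TRUE)
        for a in (5e-5, 2e-4):
            for b in (0.08, 0.12):
                for s2 in (1e-10, 0.2):
                    if (a, b) == (0.0001, 0.1):
                        continue
                    assert expected_loglik(ThetaGG(a, b, s2), self.TRUE) < best

    def test_monte_carlo_oracle(self):
        th_fit = ThetaGG(0.00012, 0.098, 0.05)
        x = sample_lifespans(1_000_000, self.TRUE, rng_seed=99)
        logf = np.log(gg_marginal_density(x, th_fit))
        mc, se = logf.mean(), logf.std(ddof=1) / np.sqrt(len(logf))
        assert expected_loglik(th_fit, self.TRUE) == pytest.approx(mc, abs=3 * se)

    def test_nearly_flat_in_small_sigma2(self):
        # curve is almost flat for sigma2 <= 0.005 relative to (0, 0.05]
        def curve(grid):
            return np.array(
                [expected_loglik(ThetaGG(0.0001, 0.1, s2), self.TRUE) for s2 in grid]
            )

        flat = curve(np.linspace(1e-6, 0.005, 9))
        wide = curve(np.linspace(1e-6, 0.05, 9))
        assert flat.max() - flat.min() < 0.1 * (wide.max() - wide.min())
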