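"""Birth-death likelihood: quadrature, closed-form oracles, BDS priors."""

import math

import numpy as np
import pytest

from mbdiv import (
    BDSParameters,
    EpochGrid,
    LineageRecord,
    bd_loglik,
    bds_log_prior,
    bds_loglik,
    constant_rate,
    integrate_rate,
    piecewise_rate,
)
from mbdiv.errors import ValidationError
from mbdiv.likelihood import _scipy_half_cauchy_logpdf


def constant_rate_closed_form(lineages, lam, mu):
    """Independent oracle: constant-rate BD likelihood in closed form.

    (n-1) origination factors (the single oldest lineage is conditioned
    upon), one extinction factor per extinct lineage, exposure
    (lam+mu) * total duration.
    """
    n = len(lineages)
    n_ext = sum(1 for l in lineages if l.te > 0)
    total = sum(l.ts - l.te for l in lineages)
    ll = -(lam + mu) * total
    if n > 1:
        if lam == 0:
            return -np.inf
        ll += (n - 1) * math.log(lam)
    if n_ext:
        if mu == 0:
            return -np.inf
        ll += n_ext * math.log(mu)
    return ll


class TestIntegrateRate:
    def test_exact_for_constants(self):
        for step in (0.3, 1.0, 7.0):
            assert integrate_rate(constant_rate(0.1), 0, 10, step) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_zero_rate(self):
        assert integrate_rate(constant_rate(0.0), 0, 10, 1.0) == 0.0

    def test_linear_rate_converges(self):
        # midpoint rule is exact for linear rates; 0.1% at step 0.01 is easy
        val = integrate_rate(lambda t: t, 0.0, 10.0, 0.01)
        assert abs(val - 50.0) / 50.0 < 1e-3

    def test_negative_interval_rejected(self):
        with pytest.raises(ValidationError):
            integrate_rate(constant_rate(1.0), 5.0, 3.0, 1.0)

    def test_quadratic_refinement_is_second_order(self):
        rate = lambda t: 0.05 * t**2 + 0.1
        exact = 0.05 * 1000 / 3 + 1.0
        e1 = abs(integrate_rate(rate, 0, 10, 1.0) - exact)
        e2 = abs(integrate_rate(rate, 0, 10, 0.5) - exact)
        assert e1 / e2 >= 3.9  # halving the step cuts the error ~4x


class TestBDLoglik:
    def test_single_extant_lineage_exposure_only(self):
        lins = [LineageRecord("A", 10.0, 0.0)]
        ll = bd_loglik(lins, constant_rate(0.1), constant_rate(0.05))
        assert ll == pytest.approx(-1.5, abs=1e-12)

    def test_two_lineage_closed_form(self, two_lineages):
        ll = bd_loglik(two_lineages, constant_rate(0.1), constant_rate(0.05))
        expected = math.log(0.1) + math.log(0.05) - 0.15 * 14
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_zero_rates_are_impossible_with_two_lineages(self, two_lineages):
        assert bd_loglik(two_lineages, constant_rate(0.0), constant_rate(0.0)) == -np.inf

    def test_matches_closed_form_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(2, 12)
            lam = float(rng.uniform(0.02, 0.5))
            mu = float(rng.uniform(0.02, 0.5))
            lins = []
            for i in range(n):
                ts = float(rng.uniform(1.0, 40.0))
                te = 0.0 if rng.random() < 0.4 else float(rng.uniform(0.0, ts * 0.9))
                if ts <= te:
                    te = 0.0
                lins.append(LineageRecord(f"t{i}", ts, te))
            ll = bd_loglik(lins, constant_rate(lam), constant_rate(mu), step=1.0)
            assert ll == pytest.approx(
                constant_rate_closed_form(lins, lam, mu), abs=1e-9
            )

    def test_oldest_tie_excludes_exactly_one(self):
        lins = [LineageRecord("A", 10.0, 0.0), LineageRecord("B", 10.0, 0.0)]
        ll = bd_loglik(lins, constant_rate(0.1), constant_rate(0.05))
        assert ll == pytest.approx(math.log(0.1) - 0.15 * 20, abs=1e-12)

    def test_monotone_decreasing_in_mu_without_extinctions(self):
        lins = [LineageRecord("A", 10.0, 0.0), LineageRecord("B", 4.0, 0.0)]
        lls = [
            bd_loglik(lins, constant_rate(0.1), constant_rate(m))
            for m in (0.01, 0.05, 0.2, 1.0)
        ]
        assert all(a > b for a, b in zip(lls, lls[1:]))

    def test_grid_refinement_convergence(self):
        lins = [LineageRecord("A", 9.0, 0.0), LineageRecord("B", 6.3, 1.2)]
        lam = lambda t: 0.1 * np.exp(0.05 * t)
        mu = lambda t: 0.04 + 0.001 * t**2
        ref = bd_loglik(lins, lam, mu, step=1e-4)
        e1 = abs(bd_loglik(lins, lam, mu, step=0.4) - ref)
        e2 = abs(bd_loglik(lins, lam, mu, step=0.2) - ref)
        assert e1 / e2 >= 3.5


class TestBDSLoglik:
    def test_one_epoch_reduces_to_constant_rate(self, two_lineages):
        grid = EpochGrid(np.array([12.0, 0.0]))
        params = BDSParameters([0.1], [0.05], 1.0, 1.0)
        expected = constant_rate_closed_form(two_lineages, 0.1, 0.05)
        assert bds_loglik(two_lineages, params, grid) == pytest.approx(
            expected, abs=1e-9
        )

    def test_refinement_with_equal_rates_is_invariant(self, two_lineages):
        one = bds_loglik(
            two_lineages,
            BDSParameters([0.1], [0.05], 1, 1),
            EpochGrid(np.array([12.0, 0.0])),
        )
        many = bds_loglik(
            two_lineages,
            BDSParameters([0.1] * 4, [0.05] * 4, 1, 1),
            EpochGrid(np.array([12.0, 9.0, 6.0, 3.0, 0.0])),
        )
        assert many == pytest.approx(one, abs=1e-9)

    def test_piecewise_exposure_by_hand(self, epoch_grid):
        lins = [LineageRecord("A", 10.0, 0.0)]
        params = BDSParameters([0.2, 0.1], [0.0, 0.0], 1.0, 1.0)
        assert bds_loglik(lins, params, epoch_grid) == pytest.approx(-1.5, abs=1e-12)

    def test_matches_generic_likelihood_with_step_rates(self, epoch_grid):
        # integer event times align the per-lineage midpoint cells with the
        # epoch boundary, so the quadrature is exact and the two paths agree
        # to floating-point precision
        rng = np.random.default_rng(7)
        for _ in range(20):
            lins = []
            for i in range(rng.integers(2, 8)):
                ts = int(rng.integers(2, 11))
                te = 0 if rng.random() < 0.5 else int(rng.integers(0, ts))
                lins.append(LineageRecord(f"t{i}", float(ts), float(te)))
            lam_k = rng.uniform(0.05, 0.4, size=2)
            mu_k = rng.uniform(0.05, 0.4, size=2)
            params = BDSParameters(lam_k, mu_k, 1.0, 1.0)
            exact = bds_loglik(lins, params, epoch_grid)
            generic = bd_loglik(
                lins,
                piecewise_rate(epoch_grid, lam_k),
                piecewise_rate(epoch_grid, mu_k),
                step=1.0,
            )
            assert generic == pytest.approx(exact, abs=1e-9)

    def test_lineages_beyond_grid_rejected(self, epoch_grid):
        lins = [LineageRecord("A", 50.0, 0.0)]
        with pytest.raises(ValidationError):
            bds_loglik(lins, BDSParameters([0.1, 0.1], [0.1, 0.1], 1, 1), epoch_grid)


class TestBDSPrior:
    def test_half_cauchy_at_zero(self):
        # density 2/(pi*s) at 0: for s=2 that is 1/pi
        params = BDSParameters([0.0], [0.0], 2.0, 2.0)
        lp = bds_log_prior(params)
        expected = 2 * math.log(1 / math.pi) + 2 * math.log(1 / 20)
        assert lp == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_parameterization(self):
        x = np.array([0.05, 0.3, 2.0])
        params = BDSParameters(x, x, 1.7, 0.4)
        lp = bds_log_prior(params)
        expected = (
            _scipy_half_cauchy_logpdf(x, 1.7).sum()
            + _scipy_half_cauchy_logpdf(x, 0.4).sum()
            + 2 * math.log(1 / 20)
        )
        assert lp == pytest.approx(expected, abs=1e-10)

    def test_scale_outside_uniform_support(self):
        assert bds_log_prior(BDSParameters([0.1], [0.1], 25.0, 1.0)) == -np.inf

    def test_negative_rate(self):
        assert bds_log_prior(BDSParameters([-0.1], [0.1], 1.0, 1.0)) == -np.inf
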