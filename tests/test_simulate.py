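import math

import numpy as np
import pytest
from scipy.optimize import brentq

from protoflux import (ConfigurationError, DivisionEvent, Lineage,
                       SpeciesCounts, default_initial_state, divide,
                       division_rate, run_lineage, steady_state_metrics,
                       step_to_division, table1)
from protoflux.rates import I_N


class TestStepToDivision:
    def test_null_model_division_time_is_analytic(self, p_null):
        """From the balanced start the null cell grows as fa(t) =
        fa0 * exp(mu t) with mu = ln 2 (the calibration), so the first
        division at fa_div = 10*fa0 happens at exactly log2(10) days."""
        traj, event = step_to_division(default_initial_state(p_null), p_null,
                                       t_max=10.0)
        assert event is not None
        assert event.time == pytest.approx(math.log2(10.0), rel=1e-6)

    def test_event_location_accuracy(self, p_default):
        _, event = step_to_division(default_initial_state(p_default),
                                    p_default, t_max=10.0)
        assert abs(event.mother_counts.fa - p_default.fa_div) / p_default.fa_div < 1e-6

    def test_dead_cell_times_out(self, p_default):
        dead = SpeciesCounts(100.0, 0.0, 10.0, 10.0, 0.0, 0.0)
        traj, event = step_to_division(dead, p_default, t_max=5.0)
        assert event is None and not traj.reached_threshold
        assert traj.final_state.fa == pytest.approx(100.0)

    def test_short_budget_times_out_below_threshold(self, p_null):
        traj, event = step_to_division(default_initial_state(p_null), p_null,
                                       t_max=1.0)
        assert event is None
        assert traj.final_state.fa < p_null.fa_div

    def test_starting_at_threshold_is_rejected(self, p_default):
        big = SpeciesCounts(p_default.fa_div, 10, 10, 10, 10, 0)
        with pytest.raises(ConfigurationError):
            step_to_division(big, p_default, t_max=1.0)


class TestDivide:
    def test_deterministic_exact_halving(self):
        mother = SpeciesCounts(100.0, 50.0, 50.0, 10.0, 2.0, 4.0)
        daughter = divide(mother)
        assert daughter == SpeciesCounts(50.0, 25.0, 25.0, 5.0, 1.0, 2.0)

    def test_halving_preserves_concentrations(self, p_default, rng):
        from protoflux import concentrations
        from conftest import random_state
        mother = random_state(rng)
        np.testing.assert_allclose(
            concentrations(divide(mother), p_default),
            concentrations(mother, p_default), rtol=1e-12)

    def test_binomial_moments(self):
        rng = np.random.default_rng(3)
        mother = SpeciesCounts(100.0, 100.0, 100.0, 100.0, 100.0, 100.0)
        draws = np.array([divide(mother, "stochastic", rng).fa
                          for _ in range(10_000)])
        # binomial(100, 1/2): mean 50, sd 5; 3 sigma of the mean estimate
        assert abs(draws.mean() - 50.0) < 3.0 * 5.0 / math.sqrt(10_000)
        assert draws.std() == pytest.approx(5.0, rel=0.1)

    def test_empty_species_stays_empty(self):
        rng = np.random.default_rng(0)
        mother = SpeciesCounts(100.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        assert divide(mother, "stochastic", rng).aa1 == 0.0

    def test_same_seed_same_outcome(self):
        mother = SpeciesCounts(101.0, 51.0, 33.0, 10.0, 5.0, 7.0)
        d1 = divide(mother, "stochastic", np.random.default_rng(42))
        d2 = divide(mother, "stochastic", np.random.default_rng(42))
        assert d1 == d2

    def test_noise_zero_recovers_half_of_rounded_counts(self):
        mother = SpeciesCounts(101.0, 51.0, 33.0, 10.0, 5.0, 7.0)
        d = divide(mother, "stochastic", np.random.default_rng(0), noise=0.0)
        np.testing.assert_array_equal(d.as_array(),
                                      np.rint(mother.as_array()) / 2.0)

    def test_stochastic_requires_rng(self):
        with pytest.raises(ConfigurationError):
            divide(SpeciesCounts(10, 1, 1, 1, 1, 1), "stochastic")


class TestRunLineage:
    def test_default_preset_divides_repeatedly(self, p_default):
        lin = run_lineage(p_default, max_divisions=15, t_budget=100.0)
        assert not lin.collapsed and len(lin.events) >= 10
        times = [ev.time for ev in lin.events]
        assert all(a < b for a, b in zip(times, times[1:]))

    def test_dead_start_collapses_with_no_events(self, p_default):
        dead = SpeciesCounts(100.0, 0.0, 10.0, 10.0, 0.0, 0.0)
        lin = run_lineage(p_default, init=dead, max_divisions=10,
                          t_budget=50.0, cycle_t_max=10.0)
        assert lin.collapsed and lin.events == []

    def test_stochastic_lineage_reproducible(self, p_default):
        kw = dict(max_divisions=10, t_budget=50.0, mode="stochastic")
        lin1 = run_lineage(p_default, rng=np.random.default_rng(7), **kw)
        lin2 = run_lineage(p_default, rng=np.random.default_rng(7), **kw)
        assert [e.time for e in lin1.events] == [e.time for e in lin2.events]
        assert lin1.events[-1].daughter_counts == lin2.events[-1].daughter_counts


def synthetic_lineage(intervals, mode="deterministic"):
    events, t = [], 0.0
    mother = SpeciesCounts(1000.0, 750.0, 750.0, 133.0, 27.0, 10.0)
    for i, dt in enumerate(intervals):
        t += dt
        events.append(DivisionEvent(time=t, mother_counts=mother,
                                    daughter_counts=divide(mother),
                                    mode=mode, cycle=i))
    return Lineage(events=events)


class TestSteadyStateMetrics:
    def test_periodic_intervals_give_reciprocal_rate(self, p_default):
        lin = synthetic_lineage([0.5] * 10)
        ss = steady_state_metrics(lin, p_default)
        assert ss.division_rate == pytest.approx(2.0)
        assert ss.converged

    def test_collapsed_lineage_reports_zero_rate(self, p_default):
        lin = Lineage(collapsed=True)
        ss = steady_state_metrics(lin, p_default)
        assert ss.division_rate == 0.0 and not ss.converged

    def test_too_few_events_is_not_converged_not_an_error(self, p_default):
        lin = synthetic_lineage([0.5, 0.5])
        ss = steady_state_metrics(lin, p_default)
        assert not ss.converged and ss.division_rate == pytest.approx(2.0)

    def test_unsettled_intervals_not_converged(self, p_default):
        lin = synthetic_lineage([1.0, 0.9, 0.8, 0.7, 0.6, 0.5])
        assert not steady_state_metrics(lin, p_default).converged


# ---------------------------------------------------------------------------
# balanced-growth oracle: an independent algebraic route to the steady rate

def balanced_growth_rate(p):
    """Fixed point of the balanced exponential-growth relations.

    In steady growth every count rises as e^(mu t) and the composition
    matches the allocation fractions; writing x for the fraction of the
    energy-currency production consumed by nucleotide synthesis, every
    concentration follows from the fractions, and x solves a scalar
    balance between trimolecular synthesis and dilution-by-growth.
    Division then occurs every ln2/mu days.  (Ignores the small
    within-cycle oscillation of [N], so it is an approximation for
    catalysed cells but exact for the null model.)
    """
    v = p.vol_per_fa

    def fractions(n_conc):
        sigma = n_conc / (p.k_sat + n_conc)
        w = p.lambdas() / (1.0 - p.k_in_array() * sigma)
        return w / w.sum()

    def mu_of(f, n_conc):
        rho = f[1] / f[0]
        kcn_eff = p.k_cn * max(0.0, 1.0 - p.alpha * max(p.k_in.values()))
        return (f[0] * p.k_fix * p.co2 * rho / (p.k_m + rho)
                * (1.0 + kcn_eff * n_conc))

    def residual(x):
        # iterate fractions/[N] to self-consistency at this x
        n_conc = 0.0
        for _ in range(200):
            f = fractions(n_conc)
            n_new = f[4] * x / (v * f[0])
            if abs(n_new - n_conc) < 1e-14:
                n_conc = n_new
                break
            n_conc = n_new
        f = fractions(n_conc)
        mu = mu_of(f, n_conc)
        conc = {
            "aa2": (f[2] / p.n_c2["aa2"] - f[4] * x) / (v * f[0]),
            "s": (f[3] / p.n_c2["s"] - f[4] * x) / (v * f[0]),
            "e": f[4] * (1.0 - x) / (v * f[0]),
        }
        nu_density = (p.k_ne * conc["aa2"] * conc["s"] * conc["e"]
                      * (1.0 + p.k_nn * n_conc))
        return nu_density - x * mu * f[4] / (v * f[0])

    x = brentq(residual, 0.0, 1.0 - 1e-12, xtol=1e-14)
    n_conc = 0.0
    for _ in range(200):
        f = fractions(n_conc)
        n_conc = f[4] * x / (v * f[0])
    return mu_of(fractions(n_conc), n_conc) / math.log(2.0)


class TestSteadyRateAgainstBalancedGrowthOracle:
    def test_null_model_rate_is_exactly_calibrated(self, p_null):
        assert division_rate(p_null, max_divisions=40,
                             t_budget=100.0) == pytest.approx(1.0, rel=1e-5)
        assert balanced_growth_rate(p_null) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("overrides", [
        dict(k_cn=0.0), dict(k_cn=10.0), dict(k_cn=1e3),
        dict(k_cn=10.0 ** 0.9, k_in={"e": 0.66}),
    ])
    def test_simulated_rate_matches_fixed_point(self, overrides):
        """The ODE lineage and the algebraic fixed point must agree to
        first order; the fixed point neglects within-cycle nucleotide
        oscillation, so agreement is approximate for catalysed cells."""
        p = table1(**overrides)
        sim = division_rate(p, max_divisions=60, t_budget=200.0)
        assert sim == pytest.approx(balanced_growth_rate(p), rel=0.15)


def test_collapse_without_carbon(p_default):
    assert division_rate(p_default.with_(co2=0.0), max_divisions=10,
                         t_budget=30.0, cycle_t_max=10.0) == 0.0


def test_division_rate_deterministic_given_params(p_default):
    r1 = division_rate(p_default, max_divisions=25, t_budget=50.0)
    r2 = division_rate(p_default, max_divisions=25, t_budget=50.0)
    assert r1 == r2
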