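"""Transition schedules and the cohort simulation."""

import numpy as np
import pytest
from scipy import optimize

from markovcea import (
    HazardRatioSet,
    LifeTable,
    ParametricSurvival,
    TransitionSchedule,
    derive_transitions,
    run_cohort,
    schedule_from_table,
)
from markovcea.config import ModelConfig
from markovcea.markov import gamma_hazard_weights, split_death_probability
from markovcea.synthetic import make_life_table


@pytest.fixture
def life_table():
    return make_life_table()


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------


class TestLifeTable:
    def test_contiguous_ages_required(self):
        with pytest.raises(ValueError, match="contiguous"):
            LifeTable(np.array([60, 62]), np.array([0.01, 0.02]),
                      np.array([0.01, 0.02]))

    def test_sex_blending(self, life_table):
        qm = life_table.q_male[life_table.ages == 70][0]
        qf = life_table.q_female[life_table.ages == 70][0]
        assert life_table.annual_probability(70, 1.0) == pytest.approx(qm)
        assert life_table.annual_probability(70, 0.0) == pytest.approx(qf)
        mid = life_table.annual_probability(70.4, 0.5)
        assert qf < mid < qm

    def test_cycle_probability_constant_hazard(self, life_table):
        q = life_table.annual_probability(80, 0.5)
        pc = life_table.cycle_probability(80, 28.0, 0.5)
        assert pc == pytest.approx(1 - (1 - q) ** (28 / 365.25))


# ---------------------------------------------------------------------------
# death split
# ---------------------------------------------------------------------------


class TestDeathSplit:
    def test_unit_ratio_gives_symmetric_split(self):
        p_sd, p_pd = split_death_probability(0.08, 0.3, 1.0)
        assert p_sd == pytest.approx(0.08, abs=1e-12)
        assert p_pd == pytest.approx(0.08, abs=1e-12)

    def test_against_independent_root_finder(self):
        """Oracle: solve the same one-dimensional problem with brentq."""
        p_os, share, r = 0.10, 0.5, 0.44

        def f(h):
            return (share * (1 - np.exp(-r * h))
                    + (1 - share) * (1 - np.exp(-h)) - p_os)

        h = optimize.brentq(f, 0.0, 10.0, xtol=1e-15)
        p_sd, p_pd = split_death_probability(p_os, share, r)
        assert p_sd == pytest.approx(1 - np.exp(-r * h), abs=1e-10)
        assert p_pd == pytest.approx(1 - np.exp(-h), abs=1e-10)

    @pytest.mark.parametrize("p_os", [0.0, 0.01, 0.1, 0.5, 0.9])
    @pytest.mark.parametrize("share", [0.0, 0.25, 0.5, 1.0])
    def test_recombination(self, p_os, share):
        p_sd, p_pd = split_death_probability(p_os, share, 0.44)
        assert share * p_sd + (1 - share) * p_pd == pytest.approx(p_os, abs=1e-10)
        assert 0 <= p_sd <= p_pd < 1


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------


class TestDeriveTransitions:
    @pytest.fixture
    def fits(self):
        pfs = ParametricSurvival(family="exponential", params={"rate": 0.09})
        os_ = ParametricSurvival(family="gamma", params={"shape": 1.6, "rate": 0.045})
        return pfs, os_

    def test_rows_stochastic_and_pd_sd_forbidden(self, fits, life_table):
        pfs, os_ = fits
        sched = derive_transitions(pfs, os_, HazardRatioSet(), life_table,
                                   "control", 300)
        for c in (0, 50, 150, 299):
            m = sched.matrix(c)
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert m[1, 0] == 0.0
            assert np.all(m[2] == [0, 0, 1])

    def test_hazard_split_recombines_to_os_probability(self, fits, life_table):
        """Occupancy-weighted death probability equals the OS cycle
        probability to 1e-10 before the background-mortality override."""
        from markovcea.survival import cycle_probability

        pfs, os_ = fits
        hrs = HazardRatioSet()
        sched = derive_transitions(pfs, os_, hrs, life_table, "control", 200)
        occ = np.array([1.0, 0.0, 0.0])
        for c in range(100):
            p_os = cycle_probability(os_, c, 28.0)
            alive = occ[0] + occ[1]
            share = occ[0] / alive
            recombined = share * sched.p_sd_d[c] + (1 - share) * sched.p_pd_d[c]
            assert recombined == pytest.approx(p_os, abs=1e-10)
            occ = occ @ sched.matrix(c)

    def test_intervention_applies_hazard_ratios(self, fits, life_table):
        pfs, os_ = fits
        hrs = HazardRatioSet()
        ctrl = derive_transitions(pfs, os_, hrs, life_table, "control", 100)
        trt = derive_transitions(pfs, os_, hrs, life_table, "intervention", 100)
        assert np.all(trt.p_pd_d[:50] < ctrl.p_pd_d[:50])
        assert trt.p_sd_pd[0] < ctrl.p_sd_pd[0]

    def test_life_table_span_enforced(self, fits):
        pfs, os_ = fits
        short = LifeTable(np.arange(60, 71), np.full(11, 0.02), np.full(11, 0.015))
        with pytest.raises(ValueError, match="life table covers"):
            derive_transitions(pfs, os_, HazardRatioSet(), short, "control", 300)


class TestScheduleFromTable:
    def test_control_cycle0_row(self, case_config):
        sched = schedule_from_table(case_config, "control", 10)
        row = sched.matrix(0)[0]
        assert row == pytest.approx([1 - 0.0854 - 0.0095, 0.0854, 0.0095])

    def test_intervention_cycle0_pd_row(self, case_config):
        sched = schedule_from_table(case_config, "intervention", 10)
        row = sched.matrix(0)[1]
        assert row == pytest.approx([0.0, 1 - 0.0116, 0.0116])

    def test_rows_sum_to_one_everywhere(self, case_config):
        sched = schedule_from_table(case_config, "control", 500)
        for c in range(0, 500, 25):
            assert np.allclose(sched.matrix(c).sum(axis=1), 1.0, atol=1e-12)

    def test_death_probabilities_follow_gamma_profile(self, case_config):
        tp = case_config.transitions
        sched = schedule_from_table(case_config, "control", 60)
        w = gamma_hazard_weights(tp.gamma_shape, tp.gamma_rate, 60, 28.0)
        expected = 1 - (1 - tp.pd_d_control) ** w
        assert np.allclose(sched.p_pd_d[:60], expected, atol=1e-12)

    def test_override_engages_once_and_stays(self, case_config):
        """The general-population floor replaces the SD death probability
        from a unique crossing cycle onward."""
        lt = case_config.life_table_object()
        n = 700
        sched = schedule_from_table(case_config, "intervention", n)
        tp = case_config.transitions
        w = gamma_hazard_weights(tp.gamma_shape, tp.gamma_rate, n, 28.0)
        model_q = 1 - (1 - tp.sd_d_intervention) ** w
        ages = 63.0 + np.arange(n) * 28.0 / 365.25
        q_lt = np.array([lt.cycle_probability(a, 28.0, 0.505) for a in ages])
        switched = sched.p_sd_d != model_q
        assert switched.any()
        first = int(np.argmax(switched))
        assert q_lt[first] > model_q[first]
        assert switched[first:].all()
        assert np.allclose(sched.p_sd_d[first:], q_lt[first:])


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def constant_schedule(p_sd_pd, p_sd_d, p_pd_d, n=10):
    return TransitionSchedule(np.full(n, p_sd_pd), np.full(n, p_sd_d),
                              np.full(n, p_pd_d))


class TestRunCohort:
    def test_two_cycle_hand_computation(self):
        """Oracle: two explicit matrix multiplications."""
        sched = constant_schedule(0.1, 0.05, 0.2, n=2)
        trace = run_cohort(sched)
        m = sched.matrix(0)
        expected = np.array([1.0, 0, 0]) @ m @ m
        assert trace.occupancy[2] == pytest.approx([0.7225, 0.165, 0.1125])
        assert trace.occupancy[2] == pytest.approx(expected)

    def test_identity_matrices_capped_at_horizon(self):
        sched = constant_schedule(0.0, 0.0, 0.0, n=2000)
        trace = run_cohort(sched)
        assert trace.occupancy[-1] == pytest.approx([1.0, 0.0, 0.0])
        assert trace.n_cycles <= 783  # 60-year guard
        assert not trace.terminated_by_absorption

    def test_absorbed_start_gives_length_one_trace(self):
        sched = constant_schedule(0.1, 0.05, 0.2, n=10)
        trace = run_cohort(sched, start=(0.0, 0.0, 1.0))
        assert trace.occupancy.shape[0] == 1
        assert trace.n_cycles == 0

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError, match="SD row exceeds"):
            constant_schedule(0.9, 0.3, 0.1)

    def test_forced_absorption_by_lethal_life_table(self, case_config):
        """Annual mortality 1.0 from age 90 absorbs every strategy by the
        age-90 cycle."""
        cfg = case_config.model_copy(deep=True)
        cfg.life_table.max_age = 90
        for arm in ("control", "intervention"):
            sched = schedule_from_table(cfg, arm, 500)
            trace = run_cohort(sched)
            age_at_end = 63.0 + trace.n_cycles * 28.0 / 365.25
            assert trace.terminated_by_absorption
            assert age_at_end <= 90.1

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_and_monotone_absorption(self, seed):
        """Occupancy sums to 1 within 1e-12 every cycle; the dead fraction
        never decreases and SD never re-fills, on random schedules."""
        rng = np.random.default_rng(seed)
        n = 50
        sched = TransitionSchedule(rng.uniform(0, 0.4, n), rng.uniform(0, 0.3, n),
                                   rng.uniform(0, 0.5, n))
        trace = run_cohort(sched)
        assert np.all(np.abs(trace.occupancy.sum(axis=1) - 1.0) < 1e-12)
        assert np.all(np.diff(trace.occ_dead) >= -1e-15)
        assert np.all(np.diff(trace.occ_sd) <= 1e-15)

    @pytest.mark.parametrize("seed", range(3))
    def test_lower_mortality_never_loses_life_years(self, seed):
        """Dominance: reducing any death probability at any cycle cannot
        reduce total life-years."""
        rng = np.random.default_rng(seed)
        n = 40
        p = rng.uniform(0, 0.3, n)
        qs = rng.uniform(0.01, 0.25, n)
        qp = rng.uniform(0.01, 0.4, n)
        base = run_cohort(TransitionSchedule(p, qs, qp))
        ly_base = (base.occ_sd[:-1] + base.occ_pd[:-1]).sum()
        for _ in range(10):
            c = rng.integers(0, n)
            qs2, qp2 = qs.copy(), qp.copy()
            if rng.random() < 0.5:
                qs2[c] *= rng.uniform(0, 1)
            else:
                qp2[c] *= rng.uniform(0, 1)
            alt = run_cohort(TransitionSchedule(p, qs2, qp2))
            ly_alt = (alt.occ_sd[:-1] + alt.occ_pd[:-1]).sum()
            assert ly_alt >= ly_base - 1e-12
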