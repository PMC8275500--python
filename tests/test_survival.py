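"""Kaplan-Meier reconstruction and parametric fitting."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markovcea import (
    DigitizedKM,
    ParametricSurvival,
    PseudoIPD,
    apply_hazard_ratio,
    cycle_probability,
    fit_parametric,
    reconstruct_ipd,
    select_best,
)
from markovcea.survival import (
    SUPPORTED_FAMILIES,
    FitError,
    ReconstructionError,
    km_survival_at,
    n_at_risk,
)
from markovcea.synthetic import SimSpec, simulate_km


# ---------------------------------------------------------------------------
# digitized-curve validation
# ---------------------------------------------------------------------------


class TestDigitizedKM:
    def test_must_start_at_origin(self):
        with pytest.raises(ReconstructionError, match="start at"):
            DigitizedKM(curve_points=[(1.0, 0.9)], risk_table=[(0, 10)])

    def test_increasing_survival_rejected(self):
        with pytest.raises(ReconstructionError, match="increases"):
            DigitizedKM(curve_points=[(0, 1.0), (2, 0.7), (4, 0.8)],
                        risk_table=[(0, 10)])

    def test_increasing_risk_counts_rejected(self):
        with pytest.raises(ReconstructionError, match="counts increase"):
            DigitizedKM(curve_points=[(0, 1.0), (2, 0.8)],
                        risk_table=[(0, 10), (3, 12)])


# ---------------------------------------------------------------------------
# Guyot reconstruction
# ---------------------------------------------------------------------------


class TestReconstruction:
    def test_no_censoring_forces_event_times(self):
        """With no censoring the step heights fully determine the IPD."""
        km = DigitizedKM(curve_points=[(0, 1.0), (2, 0.8), (5, 0.4)],
                         risk_table=[(0, 10), (6, 4)])
        ipd = reconstruct_ipd(km)
        events = sorted(t for t, e in ipd.records if e == 1)
        censored = [t for t, e in ipd.records if e == 0]
        assert events == [2.0, 2.0, 5.0, 5.0, 5.0, 5.0]
        assert len(censored) == 4 and all(t >= 5.0 for t in censored)
        assert ipd.n == 10

    def test_needs_two_risk_rows(self):
        km = DigitizedKM(curve_points=[(0, 1.0), (2, 0.8)], risk_table=[(0, 10)])
        with pytest.raises(ReconstructionError, match="2 rows"):
            reconstruct_ipd(km)

    @pytest.mark.parametrize("seed", range(6))
    def test_round_trip_matches_digitized_curve(self, seed):
        """KM of the reconstruction tracks the digitized survival to 0.01
        and the at-risk table exactly."""
        spec = SimSpec(family="exponential", params={"rate": 0.08}, n=200,
                       censor_at_months=30.0, grid_points=60, seed=seed)
        km, truth = simulate_km(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = reconstruct_ipd(km)
        grid = km.times[1:]
        err = np.max(np.abs(km_survival_at(rec, grid) - km.survival[1:]))
        assert err <= 0.01
        for t, n in km.risk_table:
            assert n_at_risk(rec, t) == n

    def test_rate_recovery_from_digitized_curve(self):
        """The generating exponential rate is recovered within 10%."""
        spec = SimSpec(family="exponential", params={"rate": 0.08}, n=200,
                       censor_at_months=30.0, grid_points=60, seed=5)
        km, truth = simulate_km(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = reconstruct_ipd(km)
        fit = fit_parametric(rec, "exponential")
        assert abs(fit.params["rate"] - 0.08) / 0.08 < 0.10
        # and the reconstruction is faithful to the *sample*: its MLE is
        # closer still to the true-data MLE
        true_fit = fit_parametric(truth["ipd"], "exponential")
        assert abs(fit.params["rate"] - true_fit.params["rate"]) \
            / true_fit.params["rate"] < 0.05

    def test_total_events_constraint(self):
        spec = SimSpec(family="exponential", params={"rate": 0.08}, n=150,
                       censor_at_months=24.0, grid_points=40, seed=3)
        km, truth = simulate_km(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = reconstruct_ipd(km, total_events=truth["n_events"])
        assert rec.n_events == truth["n_events"]


# ---------------------------------------------------------------------------
# parametric fitting
# ---------------------------------------------------------------------------

RECOVERY_PARAMS = {
    "exponential": {"rate": 0.07},
    "weibull": {"shape": 1.4, "scale": 14.0},
    "gamma": {"shape": 1.8, "rate": 0.12},
    "lognormal": {"median": 10.0, "sigma": 0.8},
    "loglogistic": {"shape": 2.0, "scale": 11.0},
    "gompertz": {"shape": 0.08, "rate": 0.04},
}


class TestFitting:
    def test_exponential_mle_is_events_over_exposure(self, exp_ipd):
        """Closed-form oracle: the exponential MLE rate is D/T exactly."""
        fit = fit_parametric(exp_ipd, "exponential")
        d = exp_ipd.n_events
        t = exp_ipd.times.sum()
        assert fit.params["rate"] == pytest.approx(d / t, rel=1e-12)

    def test_exponential_matches_lifelines(self, exp_ipd):
        """Independent oracle: lifelines' right-censored exponential fit."""
        lifelines = pytest.importorskip("lifelines")
        lf = lifelines.ExponentialFitter().fit(exp_ipd.times, exp_ipd.events)
        fit = fit_parametric(exp_ipd, "exponential")
        assert fit.params["rate"] == pytest.approx(1.0 / lf.lambda_, rel=1e-6)

    def test_weibull_matches_lifelines(self, exp_ipd):
        lifelines = pytest.importorskip("lifelines")
        lf = lifelines.WeibullFitter().fit(exp_ipd.times, exp_ipd.events)
        fit = fit_parametric(exp_ipd, "weibull")
        assert fit.params["shape"] == pytest.approx(lf.rho_, rel=1e-3)
        assert fit.params["scale"] == pytest.approx(lf.lambda_, rel=1e-3)

    @pytest.mark.parametrize("family", sorted(RECOVERY_PARAMS))
    def test_parameter_recovery(self, family):
        """Each family recovers its generating parameters within 15% at
        n=1000 with ~20% administrative censoring."""
        true = RECOVERY_PARAMS[family]
        gen = ParametricSurvival(family=family, params=true)
        rng = np.random.default_rng(7)
        times = np.asarray(gen._dist.rvs(size=1000, random_state=rng))
        cens_at = float(np.quantile(times, 0.8))
        events = (times <= cens_at).astype(int)
        times = np.minimum(times, cens_at)
        ipd = PseudoIPD(records=list(zip(times.tolist(), events.tolist())))
        fit = fit_parametric(ipd, family)
        for k, v in true.items():
            assert abs(fit.params[k] - v) / v < 0.15, (family, k, fit.params)

    def test_all_censored_refused(self):
        ipd = PseudoIPD(records=[(5.0, 0)] * 20)
        with pytest.raises(FitError, match="no events"):
            fit_parametric(ipd, "exponential")

    def test_aic_definition(self, exp_ipd):
        for family in ("exponential", "weibull"):
            fit = fit_parametric(exp_ipd, family)
            assert fit.aic == pytest.approx(
                2 * fit.n_params - 2 * fit.log_likelihood, abs=1e-9)

    @pytest.mark.parametrize("family", sorted(SUPPORTED_FAMILIES))
    def test_survival_function_shape(self, family):
        """S(0)=1 and S is non-increasing on a dense grid for every family."""
        surv = ParametricSurvival(family=family, params=RECOVERY_PARAMS[family])
        grid = np.linspace(0, 120, 600)
        s = surv.survival(grid)
        assert s[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s > 0) | (grid > 0))


class TestSelection:
    def test_single_candidate_returned(self, exp_ipd):
        fit = select_best(exp_ipd, ["weibull"])
        assert fit.family == "weibull"

    def test_exponential_data_prefers_exponential(self):
        """AIC selects the generating family in a majority of replicates."""
        wins = 0
        n_rep = 11
        for seed in range(n_rep):
            rng = np.random.default_rng(100 + seed)
            times = rng.exponential(1 / 0.08, 500)
            ipd = PseudoIPD(records=[(t, 1) for t in times.tolist()])
            best = select_best(ipd, ["exponential", "gamma"])
            wins += best.family == "exponential"
        assert wins > n_rep / 2

    def test_all_failures_raise(self):
        ipd = PseudoIPD(records=[(5.0, 0)] * 5)
        with pytest.raises(FitError, match="all candidate"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                select_best(ipd, ["exponential", "weibull"])


# ---------------------------------------------------------------------------
# cycle conversion
# ---------------------------------------------------------------------------


class TestCycleProbability:
    def test_exponential_closed_form(self):
        # 0.1/year = 0.1/12 per month... rate given per month here: use the
        # per-year rate converted to the month time unit
        rate_month = 0.1 * 28 / 365.25 / (28 / 30.4375)  # 0.1/yr in /month
        surv = ParametricSurvival(family="exponential", params={"rate": rate_month})
        p = cycle_probability(surv, 0, 28.0)
        assert p == pytest.approx(1 - np.exp(-0.1 * 28 / 365.25), rel=1e-10)
        assert p == pytest.approx(0.007637, abs=5e-6)

    def test_memoryless_constant_over_cycles(self):
        surv = ParametricSurvival(family="exponential", params={"rate": 0.05})
        ps = [cycle_probability(surv, c, 28.0) for c in range(40)]
        assert np.allclose(ps, ps[0], rtol=1e-12)

    def test_gamma_increasing_hazard_raises_probability(self):
        surv = ParametricSurvival(family="gamma", params={"shape": 2.0, "rate": 0.05})
        ps = [cycle_probability(surv, c, 28.0) for c in range(60)]
        assert np.all(np.diff(ps) > 0)

    def test_exhausted_survival_returns_one(self):
        surv = ParametricSurvival(family="weibull", params={"shape": 3.0, "scale": 1.0})
        with pytest.warns(UserWarning, match="probability 1"):
            assert cycle_probability(surv, 10 ** 4, 28.0) == 1.0


class TestHazardRatio:
    @pytest.mark.parametrize("p, hr, expected", [
        (0.0854, 1.0, 0.0854),
        (0.0854, 0.21, 0.018572),
        (0.5, 2.0, 0.75),
    ])
    def test_known_values(self, p, hr, expected):
        assert apply_hazard_ratio(p, hr) == pytest.approx(expected, abs=5e-7)

    def test_certain_event_rejected(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(1.0, 0.5)

    @given(p=st.floats(0.001, 0.999), hr=st.floats(0.01, 10.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_both_arguments(self, p, hr):
        base = apply_hazard_ratio(p, hr)
        assert 0.0 <= base < 1.0
        assert apply_hazard_ratio(min(p * 1.01, 0.9995), hr) >= base
        assert apply_hazard_ratio(p, hr * 1.01) >= base
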