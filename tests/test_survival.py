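"""Parametric survival functions, transition probabilities, MLE and selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cllcea.survival import (
    FAMILIES,
    FitError,
    FitResult,
    ParameterError,
    SurvivalDistribution,
    fit_all,
    fit_mle,
    select_best,
    survival_at,
    transition_prob,
)

# representative parameter sets per family (monthly time axis)
REPRESENTATIVE = {
    "exponential": {"rate": 0.00592451},
    "weibull": {"shape": 1.3, "rate": 0.01},
    "gompertz": {"shape": 0.02325928, "rate": 0.00943535},
    "gamma": {"shape": 1.1802239, "rate": 0.0191373},
    "lognormal": {"meanlog": 3.5, "sdlog": 0.8},
    "loglogistic": {"shape": 2.0, "scale": 40.0},
}


class TestClosedForms:
    def test_survival_starts_at_one(self):
        for fam, params in REPRESENTATIVE.items():
            assert survival_at(SurvivalDistribution(fam, **params), 0.0) == pytest.approx(1.0)

    def test_exponential_closed_form(self):
        # first-line oral-therapy progression curve: rate 0.00592451 / month
        d = SurvivalDistribution("exponential", rate=0.00592451)
        assert survival_at(d, 24) == pytest.approx(math.exp(-0.00592451 * 24), rel=1e-12)
        assert survival_at(d, 24) == pytest.approx(0.8675, abs=5e-4)

    def test_gompertz_closed_form(self):
        shape, rate = 0.02325928, 0.00943535
        d = SurvivalDistribution("gompertz", shape=shape, rate=rate)
        expected = math.exp(-(rate / shape) * (math.exp(shape * 24) - 1.0))
        assert survival_at(d, 24) == pytest.approx(expected, rel=1e-12)
        assert survival_at(d, 24) == pytest.approx(0.738, abs=1e-3)

    def test_transition_prob_exponential(self):
        d = SurvivalDistribution("exponential", rate=0.00592451)
        assert transition_prob(d, 0, 1) == pytest.approx(1 - math.exp(-0.00592451), rel=1e-12)
        # memorylessness: identical monthly probability at any age
        assert transition_prob(d, 0, 1) == pytest.approx(transition_prob(d, 57.0, 1), rel=1e-12)

    def test_gompertz_hazard_increases(self):
        d = SurvivalDistribution("gompertz", shape=0.02325928, rate=0.00943535)
        assert transition_prob(d, 60, 1) > transition_prob(d, 0, 1)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_composition_identity(self, family):
        """Two consecutive cycles compose exactly into one double-width cycle."""
        d = SurvivalDistribution(family, **REPRESENTATIVE[family])
        for t in (0.0, 5.0, 23.0, 80.0):
            delta = 1.0
            one = transition_prob(d, t, delta)
            two = transition_prob(d, t + delta, delta)
            composed = 1 - (1 - one) * (1 - two)
            assert composed == pytest.approx(transition_prob(d, t, 2 * delta), abs=1e-12)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_monotone_and_bounded(self, family):
        d = SurvivalDistribution(family, **REPRESENTATIVE[family])
        grid = np.linspace(0, 200, 2001)
        s = d.survival(grid)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))
        tp = [d.transition_prob(t, 1.0) for t in np.linspace(0, 100, 51)]
        assert all(0 <= p <= 1 for p in tp)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    family=st.sampled_from(FAMILIES),
    a=st.floats(0.2, 3.0),
    b=st.floats(0.001, 0.1),
    t=st.floats(0.0, 120.0),
)
def test_survival_invariants_property(family, a, b, t):
    """S(0)=1, S non-increasing, S in [0,1] across sampled parameters."""
    if family == "exponential":
        d = SurvivalDistribution(family, rate=b)
    elif family == "lognormal":
        d = SurvivalDistribution(family, meanlog=math.log(1 / b) / 2, sdlog=a)
    elif family == "loglogistic":
        d = SurvivalDistribution(family, shape=a, scale=1 / b)
    else:
        d = SurvivalDistribution(family, shape=a if family != "gompertz" else a / 50, rate=b)
    assert d.survival(0.0) == pytest.approx(1.0)
    s1, s2 = d.survival(t), d.survival(t + 7.5)
    assert -1e-12 <= s2 <= s1 + 1e-12 <= 1 + 1e-12


class TestValidation:
    def test_unknown_family(self):
        with pytest.raises(ParameterError):
            SurvivalDistribution("spline", knots=3)

    def test_nonpositive_rate(self):
        with pytest.raises(ParameterError):
            SurvivalDistribution("exponential", rate=-0.1)
        with pytest.raises(ParameterError):
            SurvivalDistribution("weibull", shape=0.0, rate=0.1)

    def test_wrong_parameter_names(self):
        with pytest.raises(ParameterError):
            SurvivalDistribution("exponential", scale=2.0)

    def test_negative_time_rejected(self):
        d = SurvivalDistribution("exponential", rate=0.1)
        with pytest.raises(ParameterError):
            d.survival(-1.0)
        with pytest.raises(ParameterError):
            d.transition_prob(-1.0, 1.0)


class TestFitting:
    def test_exponential_recovery(self):
        rng = np.random.default_rng(42)
        times = rng.exponential(1 / 0.006, size=5000)
        fit = fit_mle((times, np.ones_like(times, bool)), "exponential")
        assert fit.distribution.params["rate"] == pytest.approx(0.006, rel=0.05)

    def test_all_censored_is_non_identifiable(self):
        times = np.linspace(1, 10, 20)
        with pytest.raises(FitError):
            fit_mle((times, np.zeros_like(times, bool)), "exponential")

    def test_bic_prefers_true_exponential(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(1 / 0.006, size=5000)
        fits = fit_all((times, np.ones_like(times, bool)))
        assert select_best(fits, "bic").family == "exponential"

    def test_aic_prefers_true_gompertz(self):
        rng = np.random.default_rng(11)
        truth = SurvivalDistribution("gompertz", shape=0.05, rate=0.005)
        times = truth.rvs(3000, rng)
        fits = fit_all((times, np.ones_like(times, bool)))
        assert select_best(fits, "aic").family == "gompertz"

    def test_aic_bic_hand_computed_three_observations(self):
        # exponential MLE on {1,2,3} all events: rate=3/6, loglik=3*ln(0.5)-3
        fit = fit_mle((np.array([1.0, 2.0, 3.0]), np.ones(3, bool)), "exponential")
        loglik = 3 * math.log(0.5) - 3.0
        assert fit.loglik == pytest.approx(loglik, abs=1e-6)
        assert fit.aic == pytest.approx(-2 * loglik + 2.0, abs=1e-5)
        assert fit.bic == pytest.approx(-2 * loglik + math.log(3), abs=1e-5)
        assert fit.n == 3

    def test_censoring_handled(self):
        # heavy censoring must not bias the exponential fit badly
        rng = np.random.default_rng(3)
        ev = rng.exponential(100.0, size=4000)
        cen = rng.uniform(0, 120, size=4000)
        times = np.minimum(ev, cen)
        events = ev <= cen
        fit = fit_mle((times, events), "exponential")
        assert fit.distribution.params["rate"] == pytest.approx(0.01, rel=0.08)


class TestSelection:
    def _fr(self, aic, bic, family="exponential"):
        return FitResult(
            distribution=SurvivalDistribution(family, **REPRESENTATIVE[family]),
            loglik=0.0,
            aic=aic,
            bic=bic,
            n=10,
        )

    def test_minimum_wins(self):
        best = select_best([self._fr(100, 100), self._fr(90, 95)], "aic")
        assert best.aic == 90

    def test_single_fit_identity(self):
        only = self._fr(50, 50)
        assert select_best([only], "bic") is only

    def test_tie_broken_by_fewer_parameters(self):
        one = self._fr(90, 90, "exponential")  # 1 parameter
        two = self._fr(90, 90, "weibull")  # 2 parameters
        assert select_best([two, one], "aic") is one

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_best([], "aic")
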