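"""Cohort engine: cycle plan, discounting, transitions, trace invariants, oracle."""

import math

import numpy as np
import pytest

from cllcea.markov import (
    CyclePlan,
    ModelError,
    build_cycle_plan,
    discount_factor,
    line_transition_probs,
    run_cohort,
)
from cllcea.survival import SurvivalDistribution

STATE_COLS = ["efs", "tf", "line2", "line3", "allo", "bsc", "death"]


class TestCyclePlan:
    def test_ten_year_plan(self):
        plan = build_cycle_plan(10)
        assert len(plan) == 54  # 48 monthly + 6 annual
        assert plan.horizon_months == 120
        assert plan.lengths[:48] == tuple([1.0] * 48)
        assert plan.lengths[48:] == tuple([12.0] * 6)
        plan.validate()

    def test_five_year_plan(self):
        plan = build_cycle_plan(5)
        assert len(plan) == 49
        assert plan.horizon_months == 60

    def test_short_horizon_rejected(self):
        with pytest.raises(ValueError):
            build_cycle_plan(3)

    def test_non_contiguous_plan_rejected(self):
        with pytest.raises(ModelError):
            CyclePlan((0.0, 2.0), (1.0, 1.0)).validate()


class TestDiscounting:
    def test_examples(self):
        assert discount_factor(0, 0.05) == 1.0
        assert discount_factor(12, 0.05) == pytest.approx(1 / 1.05, rel=1e-12)
        assert discount_factor(77, 0.0) == 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(12, -0.01)


class TestLineTransitions:
    def test_disease_death_closed_form(self):
        os = SurvivalDistribution("exponential", rate=0.00368296)
        pfs = SurvivalDistribution("exponential", rate=0.00592451)
        p = line_transition_probs(pfs, os, 10.0, 1.0)
        assert p["die"] == pytest.approx(1 - math.exp(-0.00368296), rel=1e-12)
        assert p["stay"] + p["fail"] + p["die"] == pytest.approx(1.0, abs=1e-12)

    def test_background_floor(self):
        os = SurvivalDistribution("exponential", rate=1e-6)
        pfs = SurvivalDistribution("exponential", rate=0.01)
        floor = 1 - 0.98 ** (1 / 12)  # annual q=0.02 on a monthly cycle
        assert floor == pytest.approx(0.001683, abs=1e-6)
        p = line_transition_probs(pfs, os, 0.0, 1.0, background=floor)
        assert p["die"] == pytest.approx(floor, rel=1e-12)

    def test_identical_curves_mean_no_progression(self):
        d = SurvivalDistribution("exponential", rate=0.01)
        p = line_transition_probs(d, d, 7.0, 1.0)
        assert p["fail"] == 0.0
        assert 0.0 <= p["stay"] <= 1.0


def _quiet(inputs):
    """Strip event-independent accruals so closed forms stay simple."""
    for name in (
        "neutropenia",
        "thrombocytopenia",
        "febrile_neutropenia",
        "hypertension",
    ):
        setattr(inputs.sae.ib, name, 0.0)
        setattr(inputs.sae.beri, name, 0.0)
    inputs.costs.followup_visit = 0.0
    inputs.costs.hypertension_outpatient_year = 0.0
    return inputs


class TestEngine:
    def test_frozen_cohort_closed_form(self, inputs):
        """With no exits the whole cohort sits in EFS; QALYs reduce to a sum."""
        _quiet(inputs)
        eps = SurvivalDistribution("exponential", rate=1e-15)
        for key in ("ib1l_pfs", "ib1l_os"):
            inputs.survival[key] = eps
        trace = run_cohort(inputs, "ib")
        plan = build_cycle_plan(10)
        expected = sum(
            0.71 * dl / 12 * discount_factor(t, 0.05)
            for t, dl in zip(plan.starts, plan.lengths)
        )
        assert trace.total_qalys == pytest.approx(expected, rel=1e-9)
        assert trace.cycles["death"].iloc[-1] == pytest.approx(0.0, abs=1e-9)

    def test_immediate_death(self, inputs):
        """Certain first-cycle death leaves one cycle of utility and one EOL charge."""
        _quiet(inputs)
        lethal = SurvivalDistribution("exponential", rate=50.0)
        inputs.survival["ib1l_pfs"] = lethal
        inputs.survival["ib1l_os"] = lethal
        trace = run_cohort(inputs, "ib")
        assert trace.total_qalys == pytest.approx(0.71 / 12, abs=1e-6)
        assert trace.cost_breakdown["other"] == pytest.approx(
            inputs.costs.end_of_life, rel=1e-6
        )
        assert trace.cycles["death"].iloc[-1] == pytest.approx(1.0, abs=1e-9)

    def test_exponential_engine_oracle(self, inputs):
        """Identical exponential PFS/OS: engine totals equal the geometric
        closed form for a decaying cohort paying drug cost and end-of-life."""
        _quiet(inputs)
        r = 0.01
        d = SurvivalDistribution("exponential", rate=r)
        inputs.survival["ib1l_pfs"] = d
        inputs.survival["ib1l_os"] = d
        trace = run_cohort(inputs, "ib")

        rho = 1.05 ** (-1 / 12)
        x = math.exp(-r) * rho
        g_monthly = (1 - x**48) / (1 - x)  # sum of S(t)*disc(t), t=0..47
        g_annual = sum(
            math.exp(-r * (48 + 12 * y)) * 1.05 ** (-(48 + 12 * y) / 12) for y in range(6)
        )
        qaly = 0.71 / 12 * g_monthly + 0.71 * g_annual
        drug = inputs.costs.ib_month * (g_monthly + 12 * g_annual)
        eol = inputs.costs.end_of_life * (
            (1 - math.exp(-r)) * g_monthly + (1 - math.exp(-12 * r)) * g_annual
        )
        assert trace.total_qalys == pytest.approx(qaly, rel=1e-6)
        assert trace.total_cost == pytest.approx(drug + eol, rel=1e-6)

    @pytest.mark.parametrize("arm", ["ib", "beri"])
    def test_trace_conservation_and_absorbing_death(self, base_traces, arm):
        c = base_traces[arm].cycles
        sums = c[STATE_COLS].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert (c[STATE_COLS] >= -1e-12).all().all()
        assert (np.diff(c["death"]) >= -1e-12).all()

    def test_zero_discount_dominates_discounted(self, inputs, base_traces):
        inputs.discount_rate = 0.0
        for arm in ("ib", "beri"):
            undisc = run_cohort(inputs, arm)
            assert undisc.total_qalys >= base_traces[arm].total_qalys
            assert undisc.total_cost >= base_traces[arm].total_cost

    def test_longer_horizon_never_loses_qalys(self, inputs):
        inputs.discount_rate = 0.0
        q10 = run_cohort(inputs, "ib").total_qalys
        inputs.horizon_years = 20
        q20 = run_cohort(inputs, "ib").total_qalys
        assert q20 >= q10

    def test_unknown_strategy_rejected(self, inputs):
        with pytest.raises(ValueError):
            run_cohort(inputs, "chemo")

    def test_background_scope_all_alive_increases_mortality(self, inputs):
        base = run_cohort(inputs, "ib").cycles["death"].iloc[-1]
        inputs.options.background_mortality_scope = "all_alive"
        floored = run_cohort(inputs, "ib").cycles["death"].iloc[-1]
        assert floored >= base
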