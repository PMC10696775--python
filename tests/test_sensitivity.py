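"""Tornado analysis, PSA sampling, CEAC behaviour and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from cllcea.sensitivity import (
    ParamSpec,
    PSAResult,
    base_case,
    ceac,
    default_param_specs,
    one_way_dsa,
    run_psa,
)


class TestParamSpec:
    def test_bounds_must_bracket_base(self):
        with pytest.raises(ValueError):
            ParamSpec("x", "bsa", 1.0, 1.2, 1.4)

    def test_beta_support_enforced(self):
        with pytest.raises(ValueError):
            ParamSpec("u", "utilities.efs_oral", 0.9, 0.5, 1.4, psa="beta")

    def test_moment_matched_gamma_mean(self):
        spec = ParamSpec("c", "costs.ib_month", 2360.36, 1770.27, 2950.45, psa="gamma")
        rng = np.random.default_rng(0)
        draws = spec.sample(20000, rng)
        assert draws.mean() == pytest.approx(2360.36, rel=0.02)
        assert draws.std() == pytest.approx(spec.sd, rel=0.05)

    def test_beta_draws_within_unit_interval(self):
        spec = ParamSpec("u", "utilities.efs_oral", 0.71, 0.67, 0.75, psa="beta")
        draws = spec.sample(5000, np.random.default_rng(1))
        assert np.all((draws >= 0) & (draws <= 1))
        assert draws.mean() == pytest.approx(0.71, abs=0.005)

    def test_fixed_is_degenerate(self):
        spec = ParamSpec("r", "discount_rate", 0.05, 0.0, 0.08, psa="fixed")
        assert np.all(spec.sample(10, np.random.default_rng(2)) == 0.05)


class TestDSA:
    def test_degenerate_range_reproduces_base(self, default_inputs, base_result):
        spec = ParamSpec("pin", "costs.ib_month", 2360.36, 2360.36, 2360.36)
        [entry] = one_way_dsa(default_inputs, [spec])
        assert entry.icer_at_low == pytest.approx(base_result.icer, abs=1e-9)
        assert entry.icer_at_high == pytest.approx(base_result.icer, abs=1e-9)
        assert entry.swing == 0.0

    def test_inert_parameter_has_zero_swing(self, default_inputs):
        # body surface area is carried in the config but the canonical monthly
        # drug prices make it inert, so its swing must be exactly zero
        spec = ParamSpec("Body surface area", "bsa", 1.72, 1.50, 1.90, psa="normal")
        [entry] = one_way_dsa(default_inputs, [spec])
        assert entry.swing == 0.0

    def test_unwired_parameter_rejected(self, default_inputs):
        with pytest.raises(AttributeError):
            one_way_dsa(
                default_inputs,
                [ParamSpec("ghost", "costs.not_a_lever", 1.0, 0.5, 1.5)],
            )

    def test_entries_sorted_by_swing(self, tornado_entries):
        swings = [e.swing for e in tornado_entries]
        assert swings == sorted(swings, reverse=True)


class TestPSA:
    def test_degenerate_distributions_collapse_to_base(self, default_inputs, base_result):
        specs = [
            ParamSpec(s.name, s.path, s.base, s.low, s.high, psa="fixed")
            for s in default_param_specs(default_inputs)
        ]
        res = run_psa(default_inputs, specs, n_draws=3, seed=0)
        assert np.allclose(res.samples["dc"], base_result.delta_cost)
        assert np.allclose(res.samples["de"], base_result.delta_qalys)

    def test_seed_reproducibility(self, default_inputs):
        a = run_psa(default_inputs, n_draws=15, seed=123).samples
        b = run_psa(default_inputs, n_draws=15, seed=123).samples
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_draw_count(self, default_inputs):
        with pytest.raises(ValueError):
            run_psa(default_inputs, n_draws=0, seed=0)


class TestCEAC:
    def _toy(self, dcs, des):
        df = pd.DataFrame({"dc": dcs, "de": des})
        df["cost_ib"] = 0.0
        df["qaly_ib"] = 0.0
        df["cost_beri"] = df["dc"]
        df["qaly_beri"] = df["de"]
        return PSAResult(samples=df, seed=0, wtp=38223.34)

    def test_counting_fractions(self):
        # two of four draws favour the oral arm at wtp=50k:
        # inmb_ib = wtp*(-de) + dc
        res = self._toy([10_000, 10_000, -120_000, -120_000], [-1.0, -1.0, 1.0, 1.0])
        assert res.ceac_point(50_000) == pytest.approx(2 / 4)
        curve = ceac(res, [0, 50_000, 200_000])
        assert set(curve["p_cost_effective"]).issubset({i / 4 for i in range(5)})

    def test_all_dominant_gives_one_everywhere(self):
        res = self._toy([50_000.0] * 5, [-1.0] * 5)
        curve = ceac(res, np.linspace(0, 100_000, 11))
        assert np.all(curve["p_cost_effective"] == 1.0)
        assert res.ib_dominant_fraction() == 1.0

    def test_monotone_when_effect_sign_shared(self):
        res = self._toy([-40_000, -10_000, 5_000], [-1.0, -0.5, -0.2])
        curve = ceac(res, np.linspace(0, 120_000, 25))
        assert np.all(np.diff(curve["p_cost_effective"]) >= 0)

    def test_empty_grid_rejected(self):
        res = self._toy([1.0], [-1.0])
        with pytest.raises(ValueError):
            ceac(res, [])


def test_base_case_labels_comparator_dominated(base_result):
    """BE+RI (strategy A) costs more and yields fewer QALYs than first-line IB."""
    assert base_result.label == "dominated"
    assert base_result.delta_cost > 0
    assert base_result.delta_qalys < 0
    assert base_result.icer < 0
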