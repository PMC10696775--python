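"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way analysis re-runs the base case at each parameter's lower and upper
bound (Table-style low-high ranges, else +/-25%) holding everything else at
base, and ranks parameters by the absolute ICER swing.  The PSA draws every
uncertain parameter from a moment-matched distribution - gamma for costs,
beta for utilities/probabilities/adverse-event risks, normal for body surface
area; survival-curve parameters and the discount rate stay fixed - and
re-evaluates both strategies per draw.  Moment matching sets the mean to the
base value and the standard deviation to (high - low)/3.92, so the central
95% interval approximates the one-way range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelInputs, get_by_path, set_by_path
from .economics import CEResult, compute_icer, net_monetary_benefit
from .markov import CohortModel

__all__ = [
    "ParamSpec",
    "TornadoEntry",
    "PSAResult",
    "base_case",
    "default_param_specs",
    "one_way_dsa",
    "run_psa",
    "ceac",
]


def base_case(inputs: ModelInputs) -> CEResult:
    """Comparator order: BE+RI versus first-line ibrutinib (strategy A = BE+RI),
    so a positive cost increment with a negative QALY increment yields the
    negative ICER sign convention of the headline comparison."""
    model = CohortModel(inputs)
    ib = model.run("ib")
    beri = model.run("beri")
    return compute_icer(
        beri.total_cost, beri.total_qalys, ib.total_cost, ib.total_qalys, wtp=inputs.wtp
    )


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain model input: dotted path, base value, range, PSA family."""

    name: str
    path: str
    base: float
    low: float
    high: float
    psa: str = "fixed"  # gamma | beta | normal | fixed

    def __post_init__(self):
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: require low <= base <= high")
        if self.psa not in ("gamma", "beta", "normal", "fixed"):
            raise ValueError(f"{self.name}: unknown PSA distribution {self.psa!r}")
        if self.psa == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ValueError(f"{self.name}: beta parameters must lie in [0, 1]")
        if self.psa in ("gamma", "beta") and self.base < 0:
            raise ValueError(f"{self.name}: {self.psa} requires a non-negative base")

    @property
    def sd(self) -> float:
        return (self.high - self.low) / 3.92

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.psa == "fixed" or self.sd == 0.0:
            return np.full(n, self.base)
        if self.psa == "gamma":
            shape = (self.base / self.sd) ** 2
            scale = self.sd**2 / self.base
            return rng.gamma(shape, scale, size=n)
        if self.psa == "beta":
            m, s = self.base, self.sd
            nu = m * (1.0 - m) / s**2 - 1.0
            if nu <= 0:  # variance too large for a beta; fall back to the base
                return np.full(n, m)
            return rng.beta(m * nu, (1.0 - m) * nu, size=n)
        # normal, truncated at zero for physical quantities
        return np.maximum(rng.normal(self.base, self.sd, size=n), 1e-9)


def _pct(base: float, frac: float = 0.25) -> tuple[float, float]:
    return base * (1 - frac), base * (1 + frac)


def default_param_specs(inputs: ModelInputs) -> list[ParamSpec]:
    """The packaged uncertainty table (one-way ranges + PSA distributions)."""
    cost_psa = inputs.options.cost_psa_distribution  # gamma per table; normal variant
    c = inputs.costs
    u = inputs.utilities
    s = inputs.sae
    specs = [
        ParamSpec("ORR of OB (3rd line)", "probs.orr_ob", 0.91, 0.83, 0.96, "beta"),
        ParamSpec("P(BSC) after 1st line", "probs.bsc_after_first_line", 0.15, 0.11, 0.18, "beta"),
        ParamSpec("P(BSC) after 2nd/3rd line", "probs.bsc_after_later_lines", 0.19, 0.14, 0.24, "beta"),
        ParamSpec("IB cost per month", "costs.ib_month", c.ib_month, 1770.27, 2950.45, cost_psa),
        ParamSpec("ZB cost per month", "costs.zb_month", c.zb_month, 2205.03, 3675.05, cost_psa),
        ParamSpec("OB cost per month", "costs.ob_month", c.ob_month, 2246.74, 3744.57, cost_psa),
        ParamSpec("BE cost per month", "costs.be_month", c.be_month, 1157.32, 1928.87, cost_psa),
        ParamSpec("RI cost per month", "costs.ri_month", c.ri_month, 1348.11, 2246.84, cost_psa),
        ParamSpec("LE cost per month", "costs.le_month", c.le_month, 3802.42, 6337.36, cost_psa),
        ParamSpec("IV infusion fee", "costs.iv_infusion", c.iv_infusion, 0.17, 0.28, cost_psa),
        ParamSpec("Drug allocation fee", "costs.drug_allocation", c.drug_allocation, 0.67, 1.12, cost_psa),
        ParamSpec("Supportive drugs per cycle", "costs.supportive_per_cycle", c.supportive_per_cycle, 2027.38, 3378.96, cost_psa),
        ParamSpec("Hospitalization per cycle", "costs.hospitalization_per_cycle", c.hospitalization_per_cycle, 1091.21, 1818.69, cost_psa),
        ParamSpec("Neutropenia cost", "costs.sae_neutropenia", c.sae_neutropenia, 0.0, 815.10, cost_psa),
        ParamSpec("Thrombocytopenia cost", "costs.sae_thrombocytopenia", c.sae_thrombocytopenia, 0.0, 605.63, cost_psa),
        ParamSpec("Febrile neutropenia cost", "costs.sae_febrile_neutropenia", c.sae_febrile_neutropenia, 0.0, 4516.31, cost_psa),
        ParamSpec("Hypertension cost", "costs.sae_hypertension", c.sae_hypertension, 0.0, 968.52, cost_psa),
        ParamSpec("Hypertension outpatient per year", "costs.hypertension_outpatient_year", c.hypertension_outpatient_year, 0.0, 129.48, cost_psa),
        ParamSpec("Follow-up visit cost", "costs.followup_visit", c.followup_visit, 36.60, 61.00, cost_psa),
        ParamSpec("BSC cost per month", "costs.bsc_month", c.bsc_month, 224.96, 374.93, cost_psa),
        ParamSpec("Allo-HSCT cost", "costs.allo_hsct", c.allo_hsct, 44715.88, 74526.46, cost_psa),
        ParamSpec("End-of-life cost", "costs.end_of_life", c.end_of_life, 11711.66, 15682.52, cost_psa),
        ParamSpec("Utility EFS oral", "utilities.efs_oral", u.efs_oral, 0.67, 0.75, "beta"),
        ParamSpec("Utility EFS IV", "utilities.efs_iv", u.efs_iv, 0.63, 0.71, "beta"),
        ParamSpec("Utility PF after 1st line", "utilities.pf_after_first_line", u.pf_after_first_line, 0.62, 0.71, "beta"),
        ParamSpec("Utility relapsed lines", "utilities.relapsed_lines", u.relapsed_lines, 0.37, 0.47, "beta"),
        ParamSpec("Disutility neutropenia", "utilities.du_neutropenia", u.du_neutropenia, 0.12225, 0.195, "beta"),
        ParamSpec("Disutility thrombocytopenia", "utilities.du_thrombocytopenia", u.du_thrombocytopenia, 0.081, 0.135, "beta"),
        ParamSpec("Disutility febrile neutropenia", "utilities.du_febrile_neutropenia", u.du_febrile_neutropenia, 0.1125, 0.1875, "beta"),
        ParamSpec("Disutility hypertension", "utilities.du_hypertension", u.du_hypertension, 0.14625, 0.195, "beta"),
        ParamSpec("Neutropenia risk, BE+RI", "sae.beri.neutropenia", s.beri.neutropenia, 0.3026, 0.5043, "beta"),
        ParamSpec("Thrombocytopenia risk, BE+RI", "sae.beri.thrombocytopenia", s.beri.thrombocytopenia, 0.1108, 0.1846, "beta"),
        ParamSpec("Febrile neutropenia risk, BE+RI", "sae.beri.febrile_neutropenia", s.beri.febrile_neutropenia, 0.0554, 0.0924, "beta"),
        ParamSpec("Hypertension risk, BE+RI", "sae.beri.hypertension", s.beri.hypertension, 0.1065, 0.1775, "beta"),
        ParamSpec("Neutropenia risk, IB", "sae.ib.neutropenia", s.ib.neutropenia, 0.1125, 0.1875, "beta"),
        ParamSpec("Thrombocytopenia risk, IB", "sae.ib.thrombocytopenia", s.ib.thrombocytopenia, 0.05, 0.0834, "beta"),
        ParamSpec("Febrile neutropenia risk, IB", "sae.ib.febrile_neutropenia", s.ib.febrile_neutropenia, 0.0125, 0.0209, "beta"),
        ParamSpec("Hypertension risk, IB", "sae.ib.hypertension", s.ib.hypertension, 0.2208, 0.3680, "beta"),
        ParamSpec("Body surface area", "bsa", inputs.bsa, 1.50, 1.90, "normal"),
        ParamSpec("Discount rate", "discount_rate", inputs.discount_rate, 0.0, 0.08, "fixed"),
    ]
    return specs


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    path: str
    icer_at_low: float
    icer_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def one_way_dsa(
    inputs: ModelInputs, specs: list[ParamSpec] | None = None
) -> list[TornadoEntry]:
    """Re-run the comparison at each parameter bound; sort by ICER swing."""
    if specs is None:
        specs = default_param_specs(inputs)
    entries = []
    for spec in specs:
        get_by_path(inputs, spec.path)  # raises if the lever is not wired
        results = {}
        for bound, value in (("low", spec.low), ("high", spec.high)):
            trial = inputs.copy()
            set_by_path(trial, spec.path, value)
            results[bound] = base_case(trial).icer
        entries.append(TornadoEntry(spec.name, spec.path, results["low"], results["high"]))
    return sorted(entries, key=lambda e: -e.swing)


def tornado_frame(entries: list[TornadoEntry], top: int = 15) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.name,
                "icer_low": e.icer_at_low,
                "icer_high": e.icer_at_high,
                "swing": e.swing,
            }
            for e in entries[:top]
        ]
    )


@dataclass
class PSAResult:
    """Monte-Carlo draws: per-strategy totals and BE+RI-vs-IB increments."""

    samples: pd.DataFrame  # draw, cost_ib, qaly_ib, cost_beri, qaly_beri, dc, de
    seed: int
    wtp: float

    @property
    def n(self) -> int:
        return len(self.samples)

    def ib_dominant_fraction(self) -> float:
        """Share of draws where IB is cheaper and more effective."""
        s = self.samples
        return float(((s["dc"] > 0) & (s["de"] < 0)).mean())

    def ceac_point(self, wtp: float) -> float:
        """P(IB cost-effective at `wtp`) = share of draws with positive
        incremental net monetary benefit for IB."""
        s = self.samples
        inmb_ib = wtp * (-s["de"]) - (-s["dc"])  # IB minus BE+RI
        return float((inmb_ib > 0).mean())


def run_psa(
    inputs: ModelInputs,
    specs: list[ParamSpec] | None = None,
    n_draws: int = 1000,
    seed: int = 0,
) -> PSAResult:
    """Monte-Carlo PSA: joint independent parameter draws, model run per draw."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if specs is None:
        specs = default_param_specs(inputs)
    rng = np.random.default_rng(seed)
    draws = {spec.path: spec.sample(n_draws, rng) for spec in specs}
    rows = []
    for i in range(n_draws):
        trial = inputs.copy()
        for path, values in draws.items():
            set_by_path(trial, path, float(values[i]))
        model = CohortModel(trial)
        ib = model.run("ib")
        beri = model.run("beri")
        rows.append(
            {
                "draw": i,
                "cost_ib": ib.total_cost,
                "qaly_ib": ib.total_qalys,
                "cost_beri": beri.total_cost,
                "qaly_beri": beri.total_qalys,
            }
        )
    df = pd.DataFrame(rows)
    df["dc"] = df["cost_beri"] - df["cost_ib"]
    df["de"] = df["qaly_beri"] - df["qaly_ib"]
    return PSAResult(samples=df, seed=seed, wtp=inputs.wtp)


def ceac(result: PSAResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve for the IB strategy."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("ceac requires a non-empty willingness-to-pay grid")
    return pd.DataFrame(
        {"wtp": grid, "p_cost_effective": [result.ceac_point(w) for w in grid]}
    )
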