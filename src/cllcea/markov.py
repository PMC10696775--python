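"""Semi-Markov cohort engine for the multi-line CLL treatment pathways.

The published four-state diagram (event-free survival, transient treatment
failure, post-treatment failure, death) compresses all relapsed therapy into
one PF box.  The engine expands PF into sub-states with their own clocks -
second line, third line, allogeneic transplant and best supportive care - so
that each line's progression-free and overall survival curves apply from line
entry.  Line clocks are tracked with tunnel compartments keyed by entry cycle,
which keeps the cohort update exact under the mixed cycle plan (monthly cycles
for the first four years, annual cycles thereafter; annual transition
probabilities come from survival ratios at the yearly boundaries rather than
compounded monthly values).

Accrual convention: state occupancy earns its full cycle cost/QALY at the
cycle start, discounted with the cycle-start factor (1+r)^(-t/12); no
half-cycle correction (an optional switch exists).  End-of-life cost is
charged to the fraction dying in a cycle at that cycle's discount factor; the
transplant lump sum is charged on entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import costing
from .survival import SurvivalDistribution

__all__ = [
    "CyclePlan",
    "LifeTable",
    "CohortTrace",
    "ModelError",
    "build_cycle_plan",
    "discount_factor",
    "line_transition_probs",
    "CohortModel",
    "run_cohort",
]

MONTHLY_PHASE_MONTHS = 48
ENTRY_AGE_YEARS = 70  # cohort age at model entry (trial median 70-71)
ORR_OB_REFERENCE = 0.91  # anchors the response-rate hazard lever at 1.0

STATE_COLUMNS = ["efs", "tf", "line2", "line3", "allo", "bsc", "death"]
COST_CATEGORIES = ["first_line", "subsequent", "ae", "other"]


class ModelError(RuntimeError):
    """Internal model inconsistency (negative residual probability, leakage...)."""


@dataclass(frozen=True)
class CyclePlan:
    """Contiguous cycle schedule: (start month, length months) per cycle."""

    starts: tuple[float, ...]
    lengths: tuple[float, ...]

    def __len__(self):
        return len(self.starts)

    @property
    def horizon_months(self) -> float:
        return self.starts[-1] + self.lengths[-1]

    def validate(self):
        for i in range(len(self.starts) - 1):
            if abs(self.starts[i] + self.lengths[i] - self.starts[i + 1]) > 1e-9:
                raise ModelError("cycle plan must be contiguous and non-overlapping")


def build_cycle_plan(horizon_years: int = 10) -> CyclePlan:
    """Monthly cycles for 4 years then annual cycles to the horizon.

    A 10-year horizon gives 48 monthly + 6 annual = 54 cycles over 120 months.
    """
    if horizon_years < 5:
        raise ValueError("horizon must be at least 5 whole years")
    starts = [float(m) for m in range(MONTHLY_PHASE_MONTHS)]
    lengths = [1.0] * MONTHLY_PHASE_MONTHS
    for y in range(horizon_years - 4):
        starts.append(float(MONTHLY_PHASE_MONTHS + 12 * y))
        lengths.append(12.0)
    plan = CyclePlan(tuple(starts), tuple(lengths))
    plan.validate()
    return plan


def discount_factor(t_months: float, annual_rate: float) -> float:
    """Present-value factor (1+r)^(-t/12) at a cycle start time."""
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    if t_months < 0:
        raise ValueError("time must be >= 0")
    return float((1.0 + annual_rate) ** (-t_months / 12.0))


class LifeTable:
    """Abridged all-cause annual mortality by single year of age."""

    def __init__(self, ages, annual_q):
        self.ages = np.asarray(ages, dtype=int)
        self.annual_q = np.asarray(annual_q, dtype=float)
        if self.ages.shape != self.annual_q.shape or self.ages.size == 0:
            raise ValueError("life table needs matching age/probability arrays")
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("life-table ages must be contiguous single years")
        if np.any((self.annual_q < 0) | (self.annual_q > 1)):
            raise ValueError("annual mortality probabilities must lie in [0, 1]")

    def q_at(self, age: float) -> float:
        idx = int(np.clip(int(age) - self.ages[0], 0, self.ages.size - 1))
        return float(self.annual_q[idx])

    def prob(self, age: float, months: float) -> float:
        """Death probability over `months` at attained age (annual q rescaled)."""
        return 1.0 - (1.0 - self.q_at(age)) ** (months / 12.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "annual_q": self.annual_q})


def line_transition_probs(
    pfs: SurvivalDistribution,
    os: SurvivalDistribution,
    t_in_line: float,
    delta: float,
    background: float = 0.0,
    hazard_multiplier: float = 1.0,
) -> dict[str, float]:
    """Per-cycle {stay, fail, die} for one treatment line.

    ``die`` is the larger of the line's overall-survival transition probability
    and the background (life-table) probability; ``fail`` is the progression
    probability net of death.  The progression hazard may be scaled by
    ``hazard_multiplier`` (response-rate lever for the third-line agent).
    """
    p_die = max(os.transition_prob(t_in_line, delta), background)
    ratio = 1.0 - pfs.transition_prob(t_in_line, delta)
    p_event = 1.0 - ratio**hazard_multiplier
    p_fail = max(0.0, p_event - p_die)
    stay = 1.0 - p_fail - p_die
    if stay < -1e-9:
        raise ModelError(
            f"negative residual stay probability ({stay:.3e}) at t={t_in_line}"
        )
    return {"stay": max(stay, 0.0), "fail": p_fail, "die": p_die}


@dataclass
class CohortTrace:
    """Per-cycle occupancy and discounted accruals for one strategy."""

    strategy: str
    cycles: pd.DataFrame

    @property
    def total_cost(self) -> float:
        return float(self.cycles["cost_total"].sum())

    @property
    def total_qalys(self) -> float:
        return float(self.cycles["qaly"].sum())

    @property
    def cost_breakdown(self) -> dict[str, float]:
        return {c: float(self.cycles[f"cost_{c}"].sum()) for c in COST_CATEGORIES}

    def occupancy(self) -> pd.DataFrame:
        return self.cycles[["cycle", "t_start", "length"] + STATE_COLUMNS]


# compartment keys -----------------------------------------------------------
# ("efs",)              first-line, clock = model time
# ("tf", from_line)     transient failure; from_line in {1, 2, 3, 4} (4 = allo)
# ("line", i, c_entry)  relapsed line i in {2, 3}, entered at cycle c_entry
# ("allo", c_entry)     allogeneic transplant compartment
# ("bsc",) / ("death",)


class CohortModel:
    """Runs the cohort trace for one parameter set (see config.ModelInputs)."""

    _surv_cache: dict[tuple, np.ndarray] = {}

    def __init__(self, inputs):
        self.inputs = inputs
        self.plan = build_cycle_plan(inputs.horizon_years)
        inputs.validate()

    # -- survival lookup ----------------------------------------------------

    def _curve(self, dist: SurvivalDistribution) -> np.ndarray:
        key = (dist, int(self.plan.horizon_months))
        arr = CohortModel._surv_cache.get(key)
        if arr is None:
            grid = np.arange(int(self.plan.horizon_months) + 13, dtype=float)
            arr = np.asarray(dist.survival(grid), dtype=float)
            CohortModel._surv_cache[key] = arr
        return arr

    def _lines_for(self, arm: str):
        s = self.inputs.survival
        zb_os = self.inputs.options.zb_os_override or s["zb_os"]
        orr_mult = ORR_OB_REFERENCE / self.inputs.probs.orr_ob
        if arm == "ib":
            return {
                1: (s["ib1l_pfs"], s["ib1l_os"], 1.0),
                2: (s["zb_pfs"], zb_os, 1.0),
                3: (s["zb_pfs"], zb_os, orr_mult),
            }
        return {
            1: (s["beri1l_pfs"], s["beri1l_os"], 1.0),
            2: (s["ib2l_pfs"], s["ib2l_os"], 1.0),
            3: (s["zb_pfs"], zb_os, 1.0),
        }

    def _tp(self, curves, tau0: int, tau1: int, mult: float = 1.0) -> float:
        arr = curves
        if arr[tau0] <= 0.0:
            return 1.0
        ratio = arr[tau1] / arr[tau0]
        if mult != 1.0:
            ratio = ratio**mult
        return float(1.0 - ratio)

    def _background(self, t0: float, dt: float) -> float:
        age = ENTRY_AGE_YEARS + t0 / 12.0
        return self.inputs.life_table.prob(age, dt)

    def _allo_probs(self, tau0: int, dt: int) -> tuple[float, float]:
        a = self.inputs.allo
        stay_rel = stay_nrm = 1.0
        for m in range(tau0, tau0 + dt):
            rel = a.relapse_monthly_early if m < a.relapse_early_months else a.relapse_monthly_late
            nrm = a.nrm_monthly_early if m < a.nrm_early_months else a.nrm_monthly_late
            stay_rel *= 1.0 - rel
            stay_nrm *= 1.0 - nrm
        return 1.0 - stay_rel, 1.0 - stay_nrm

    # -- main loop ----------------------------------------------------------

    def run(self, strategy: str) -> CohortTrace:
        if strategy not in ("ib", "beri"):
            raise ValueError(f"unknown strategy {strategy!r}; expected 'ib' or 'beri'")
        inp = self.inputs
        plan = self.plan
        costs, u = inp.costs, inp.utilities
        risks = inp.sae.for_arm(strategy)
        lines = self._lines_for(strategy)
        curves = {
            i: (self._curve(pfs), self._curve(os), mult)
            for i, (pfs, os, mult) in lines.items()
        }
        bsc_p = {
            1: inp.probs.bsc_after_first_line,
            2: inp.probs.bsc_after_later_lines,
            3: inp.probs.bsc_after_later_lines,
        }
        scope_all = inp.options.background_mortality_scope == "all_alive"
        half_cycle = inp.options.half_cycle_correction

        comps: dict[tuple, float] = {("efs",): 1.0}
        rows = []
        for c in range(len(plan)):
            t0, dt = plan.starts[c], plan.lengths[c]
            idt = int(dt)
            it0 = int(t0)
            disc = discount_factor(t0, inp.discount_rate)
            disc_mid = discount_factor(t0 + dt / 2.0, inp.discount_rate)
            acc_disc = disc_mid if half_cycle else disc
            bg = self._background(t0, dt)

            occ = {s: 0.0 for s in STATE_COLUMNS}
            cost = dict.fromkeys(COST_CATEGORIES, 0.0)
            qaly = 0.0
            flows: dict[tuple, float] = {}
            deaths = 0.0

            def add_flow(key, mass):
                flows[key] = flows.get(key, 0.0) + mass

            alive = 1.0 - comps.get(("death",), 0.0)
            followers = 0.0  # occupancy eligible for routine follow-up visits

            for key, mass in comps.items():
                if mass <= 0.0:
                    continue
                kind = key[0]
                if kind == "efs":
                    occ["efs"] += mass
                    drug, delivery = costing.efs_drug_and_delivery_cost(
                        strategy, it0, idt, costs
                    )
                    cost["first_line"] += mass * (drug + delivery) * acc_disc
                    um = costing.efs_utility_months(strategy, it0, idt, u)
                    qaly += mass * um / 12.0 * acc_disc
                    if c == 0:
                        cost["ae"] += mass * costing.sae_expected_cost(risks, costs) * acc_disc
                        qaly -= mass * costing.sae_expected_disutility(risks, u) / 12.0 * acc_disc
                    followers += mass
                    pfs_c, os_c, mult = curves[1]
                    die_dis = self._tp(os_c, it0, it0 + idt)
                    p_die = max(die_dis, bg) if scope_all else die_dis
                    p_event = self._tp(pfs_c, it0, it0 + idt, mult)
                    p_fail = max(0.0, p_event - p_die)
                    if p_fail + p_die > 1.0 + 1e-9:
                        raise ModelError("first-line exit probabilities exceed 1")
                    add_flow(("efs",), mass * (1.0 - p_fail - p_die))
                    add_flow(("tf", 1), mass * p_fail)
                    add_flow(("death",), mass * p_die)
                    deaths += mass * p_die
                elif kind == "tf":
                    from_line = key[1]
                    occ["tf"] += mass
                    ut = u.pf_after_first_line if from_line == 1 else u.relapsed_lines
                    qaly += mass * ut * dt / 12.0 * acc_disc
                    followers += mass
                    if from_line == 4:  # transplant failure -> all to BSC
                        add_flow(("bsc",), mass)
                    else:
                        p_bsc = bsc_p[from_line]
                        add_flow(("bsc",), mass * p_bsc)
                        if from_line < 3:
                            add_flow(("line", from_line + 1, c + 1), mass * (1.0 - p_bsc))
                        else:
                            add_flow(("allo", c + 1), mass * (1.0 - p_bsc))
                elif kind == "line":
                    li, c_entry = key[1], key[2]
                    occ[f"line{li}"] += mass
                    cost["subsequent"] += (
                        mass * costing.line_drug_monthly(strategy, li, costs) * dt * acc_disc
                    )
                    qaly += mass * u.relapsed_lines * dt / 12.0 * acc_disc
                    followers += mass
                    tau0 = it0 - int(plan.starts[c_entry])
                    pfs_c, os_c, mult = curves[li]
                    p_die = max(self._tp(os_c, tau0, tau0 + idt), bg)
                    p_event = self._tp(pfs_c, tau0, tau0 + idt, mult)
                    p_fail = max(0.0, p_event - p_die)
                    add_flow(key, mass * (1.0 - p_fail - p_die))
                    add_flow(("tf", li), mass * p_fail)
                    add_flow(("death",), mass * p_die)
                    deaths += mass * p_die
                elif kind == "allo":
                    c_entry = key[1]
                    occ["allo"] += mass
                    if c_entry == c:  # transplant lump sum on entry
                        cost["other"] += mass * costs.allo_hsct * acc_disc
                    qaly += mass * u.relapsed_lines * dt / 12.0 * acc_disc
                    followers += mass
                    tau0 = it0 - int(plan.starts[c_entry])
                    p_rel, p_nrm = self._allo_probs(tau0, idt)
                    p_die = max(p_nrm, bg)
                    p_rel = min(p_rel, 1.0 - p_die)
                    add_flow(key, mass * (1.0 - p_rel - p_die))
                    add_flow(("tf", 4), mass * p_rel)
                    add_flow(("death",), mass * p_die)
                    deaths += mass * p_die
                elif kind == "bsc":
                    occ["bsc"] += mass
                    cost["other"] += mass * costs.bsc_month * dt * acc_disc
                    qaly += mass * u.relapsed_lines * dt / 12.0 * acc_disc
                    p_die = bg
                    add_flow(("bsc",), mass * (1.0 - p_die))
                    add_flow(("death",), mass * p_die)
                    deaths += mass * p_die
                elif kind == "death":
                    occ["death"] += mass
                    add_flow(("death",), mass)
                else:  # pragma: no cover
                    raise ModelError(f"unknown compartment {key!r}")

            # cross-state accruals
            visits = costing.followup_visits(t0, t0 + dt)
            cost["other"] += followers * visits * costs.followup_visit * acc_disc
            cost["ae"] += (
                risks.hypertension
                * alive
                * costs.hypertension_outpatient_year
                * dt
                / 12.0
                * acc_disc
            )
            cost["other"] += deaths * costs.end_of_life * acc_disc

            total_mass = sum(occ.values())
            if abs(total_mass - 1.0) > 1e-9:
                raise ModelError(f"occupancy leakage at cycle {c}: sum={total_mass!r}")

            rows.append(
                {
                    "cycle": c,
                    "t_start": t0,
                    "length": dt,
                    **occ,
                    **{f"cost_{k}": v for k, v in cost.items()},
                    "cost_total": sum(cost.values()),
                    "qaly": qaly,
                }
            )
            comps = {k: v for k, v in flows.items() if v > 0.0}

        return CohortTrace(strategy=strategy, cycles=pd.DataFrame(rows))


def run_cohort(inputs, strategy: str) -> CohortTrace:
    """Convenience wrapper: build the engine and run one strategy."""
    return CohortModel(inputs).run(strategy)
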