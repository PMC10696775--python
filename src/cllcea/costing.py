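"""Cost and utility accrual rules for the two treatment pathways.

All monetary amounts are 2022 US dollars.  Drug acquisition uses the printed
per-month prices (a "month" being one 28-day dosing block); per-milligram
prices are carried in the config for reference but are not part of accrual.

Pathways:

* ``ib`` arm - first-line ibrutinib (oral, until progression), second-line
  zanubrutinib, third-line orelabrutinib.
* ``beri`` arm - six 28-day cycles of bendamustine + rituximab with
  hospitalisation, supportive drugs and administration fees, followed by oral
  lenalidomide maintenance (dose-escalated 5/10/15 mg over cycles 7, 8-12 and
  onwards, priced as 1/3, 2/3 and the full monthly price) until progression;
  second-line ibrutinib, third-line zanubrutinib.

Severe (grade >=3) adverse events are charged as an expected one-off cost and
a one-month expected disutility in the first cycle of first-line treatment;
the fraction with hypertension additionally accrues annual outpatient costs
for the rest of their lives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CostInputs",
    "UtilityInputs",
    "SAERisks",
    "SAEProfile",
    "CPIAdjuster",
    "followup_visits",
    "sae_expected_cost",
    "sae_expected_disutility",
    "efs_drug_and_delivery_cost",
    "efs_utility_months",
    "line_drug_monthly",
]

# months of chemoimmunotherapy delivery in the BE+RI arm (cycles 1-6)
CHEMO_MONTHS = 6
# intravenous administrations per 28-day chemo cycle: BE on days 1-2, RI once
INFUSIONS_PER_CYCLE = 3
ALLOCATIONS_PER_CYCLE = 3


@dataclass
class CostInputs:
    """Unit costs (2022 USD); Table-driven defaults live in config.default_inputs."""

    # monthly drug acquisition (canonical)
    ib_month: float
    zb_month: float
    ob_month: float
    be_month: float
    ri_month: float
    le_month: float
    # per-mg list prices (reference only, not accrued)
    ib_mg: float
    zb_mg: float
    ob_mg: float
    be_mg: float
    ri_mg: float
    le_mg: float
    # administration & inpatient
    iv_infusion: float
    drug_allocation: float
    supportive_per_cycle: float
    hospitalization_per_cycle: float
    # severe adverse events
    sae_neutropenia: float
    sae_thrombocytopenia: float
    sae_febrile_neutropenia: float
    sae_hypertension: float
    hypertension_outpatient_year: float
    # follow-up / terminal care
    followup_visit: float
    bsc_month: float
    allo_hsct: float
    end_of_life: float

    def validate(self):
        for name, value in vars(self).items():
            if value < 0:
                raise ValueError(f"cost input {name!r} must be >= 0")


@dataclass
class UtilityInputs:
    """Health-state utilities and SAE disutility magnitudes."""

    efs_oral: float = 0.71
    efs_iv: float = 0.67
    pf_after_first_line: float = 0.66
    relapsed_lines: float = 0.42
    death: float = 0.0
    du_neutropenia: float = 0.163
    du_thrombocytopenia: float = 0.108
    du_febrile_neutropenia: float = 0.15
    du_hypertension: float = 0.195

    def validate(self):
        for name in ("efs_oral", "efs_iv", "pf_after_first_line", "relapsed_lines", "death"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"utility {name!r} must lie in [0, 1]")
        for name in vars(self):
            if name.startswith("du_") and getattr(self, name) < 0:
                raise ValueError(f"disutility magnitude {name!r} must be >= 0")


@dataclass
class SAERisks:
    """Grade >=3 adverse-event risks for one strategy (fractions)."""

    neutropenia: float
    thrombocytopenia: float
    febrile_neutropenia: float
    hypertension: float

    def validate(self):
        for name, v in vars(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"SAE risk {name!r} must lie in [0, 1]")


@dataclass
class SAEProfile:
    ib: SAERisks
    beri: SAERisks

    def for_arm(self, arm: str) -> SAERisks:
        if arm not in ("ib", "beri"):
            raise ValueError(f"unknown strategy {arm!r}")
        return getattr(self, arm)

    def validate(self):
        self.ib.validate()
        self.beri.validate()


@dataclass
class CPIAdjuster:
    """Health-CPI inflation to 2022 plus CNY->USD conversion at the 2022 mean rate.

    The packaged index series is a smooth synthetic approximation of the Chinese
    health CPI (the analysis inputs are already expressed in 2022 USD, so the
    adjuster is a convenience for bringing older local charges on-scale).
    """

    exchange_rate_cny_per_usd: float = 6.7261
    health_cpi: dict[int, float] = field(
        default_factory=lambda: {
            2015: 100.0,
            2016: 103.8,
            2017: 109.4,
            2018: 114.2,
            2019: 116.9,
            2020: 119.0,
            2021: 119.4,
            2022: 120.1,
        }
    )

    def adjust(self, amount: float, from_year: int, currency: str = "USD") -> float:
        if from_year not in self.health_cpi:
            raise KeyError(f"no CPI index for year {from_year}")
        usd = amount
        if currency.upper() == "CNY":
            usd = amount / self.exchange_rate_cny_per_usd
        elif currency.upper() != "USD":
            raise ValueError(f"unsupported currency {currency!r}")
        return usd * self.health_cpi[2022] / self.health_cpi[from_year]


def followup_visits(t_start: float, t_end: float) -> int:
    """Scheduled routine visits in [t_start, t_end) months.

    Every 3 months in the first two years, every 6 months in years 3-5, then
    annually.
    """
    count = 0
    m = int(t_start)
    while m < t_end:
        if m < 24:
            scheduled = m % 3 == 0
        elif m < 60:
            scheduled = m % 6 == 0
        else:
            scheduled = m % 12 == 0
        if scheduled and m >= t_start:
            count += 1
        m += 1
    return count


def sae_expected_cost(risks: SAERisks, costs: CostInputs) -> float:
    """Expected one-off SAE treatment cost per patient starting first line."""
    return (
        risks.neutropenia * costs.sae_neutropenia
        + risks.thrombocytopenia * costs.sae_thrombocytopenia
        + risks.febrile_neutropenia * costs.sae_febrile_neutropenia
        + risks.hypertension * costs.sae_hypertension
    )


def sae_expected_disutility(risks: SAERisks, u: UtilityInputs) -> float:
    """Expected utility decrement (magnitude) applied for one month."""
    return (
        risks.neutropenia * u.du_neutropenia
        + risks.thrombocytopenia * u.du_thrombocytopenia
        + risks.febrile_neutropenia * u.du_febrile_neutropenia
        + risks.hypertension * u.du_hypertension
    )


def _beri_month_cost(month: int, costs: CostInputs) -> tuple[float, float]:
    """(drug, delivery) cost of one BE+RI-arm first-line month."""
    if month < CHEMO_MONTHS:
        drug = costs.be_month + costs.ri_month
        delivery = (
            costs.supportive_per_cycle
            + costs.hospitalization_per_cycle
            + INFUSIONS_PER_CYCLE * costs.iv_infusion
            + ALLOCATIONS_PER_CYCLE * costs.drug_allocation
        )
        return drug, delivery
    if month == CHEMO_MONTHS:  # lenalidomide 5 mg escalation cycle
        return costs.le_month / 3.0, 0.0
    if month < 12:  # 10 mg, cycles 8-12
        return costs.le_month * 2.0 / 3.0, 0.0
    return costs.le_month, 0.0


def efs_drug_and_delivery_cost(
    arm: str, month_start: int, n_months: int, costs: CostInputs
) -> tuple[float, float]:
    """Undiscounted first-line (drug, delivery) cost over a cycle window."""
    if arm == "ib":
        return costs.ib_month * n_months, 0.0
    drug = delivery = 0.0
    for m in range(month_start, month_start + n_months):
        d, dl = _beri_month_cost(m, costs)
        drug += d
        delivery += dl
    return drug, delivery


def efs_utility_months(
    arm: str, month_start: int, n_months: int, u: UtilityInputs
) -> float:
    """Utility-weighted months in the first-line (event-free) state."""
    if arm == "ib":
        return u.efs_oral * n_months
    total = 0.0
    for m in range(month_start, month_start + n_months):
        total += u.efs_iv if m < CHEMO_MONTHS else u.efs_oral
    return total


def line_drug_monthly(arm: str, line_index: int, costs: CostInputs) -> float:
    """Monthly acquisition cost of the drug given in a relapsed line (2 or 3)."""
    table = {
        ("ib", 2): costs.zb_month,
        ("ib", 3): costs.ob_month,
        ("beri", 2): costs.ib_month,
        ("beri", 3): costs.zb_month,
    }
    try:
        return table[(arm, line_index)]
    except KeyError:
        raise ValueError(f"no drug defined for arm {arm!r} line {line_index}")
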