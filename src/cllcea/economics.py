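"""Incremental cost-effectiveness outputs: ICER, dominance, net monetary benefit."""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["CEResult", "compute_icer", "net_monetary_benefit"]


@dataclass(frozen=True)
class CEResult:
    """Comparison of strategy A against comparator B.

    ``delta_cost = cost_a - cost_b`` and ``delta_qalys = qaly_a - qaly_b``;
    ``icer`` is their ratio (NaN when the QALY difference is exactly zero) and
    ``label`` classifies strategy A: "dominant" (cheaper and more effective),
    "dominated" (costlier and less effective), "cost-effective" /
    "not cost-effective" by comparison with the willingness-to-pay threshold,
    or "equivalent".
    """

    cost_a: float
    qaly_a: float
    cost_b: float
    qaly_b: float
    delta_cost: float
    delta_qalys: float
    icer: float
    label: str
    wtp: float

    def as_dict(self) -> dict:
        return {
            "cost_a": self.cost_a,
            "qaly_a": self.qaly_a,
            "cost_b": self.cost_b,
            "qaly_b": self.qaly_b,
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "icer": self.icer,
            "label": self.label,
            "wtp": self.wtp,
        }


def compute_icer(
    cost_a: float,
    qaly_a: float,
    cost_b: float,
    qaly_b: float,
    wtp: float = 38_223.34,
) -> CEResult:
    """Incremental cost-effectiveness of strategy A versus comparator B."""
    for v in (cost_a, qaly_a, cost_b, qaly_b):
        if not math.isfinite(v):
            raise ValueError("cost/QALY totals must be finite")
    dc = cost_a - cost_b
    de = qaly_a - qaly_b
    if de == 0.0 and dc == 0.0:
        return CEResult(cost_a, qaly_a, cost_b, qaly_b, dc, de, math.nan, "equivalent", wtp)
    if de == 0.0:
        label = "dominated" if dc > 0 else "dominant"
        return CEResult(cost_a, qaly_a, cost_b, qaly_b, dc, de, math.nan, label, wtp)
    icer = dc / de
    if dc < 0 and de > 0:
        label = "dominant"
    elif dc > 0 and de < 0:
        label = "dominated"
    elif dc <= 0 and de < 0:
        # A cheaper but less effective: cost saved per QALY forgone vs threshold
        label = "cost-effective" if icer > wtp else "not cost-effective"
    else:
        label = "cost-effective" if icer <= wtp else "not cost-effective"
    return CEResult(cost_a, qaly_a, cost_b, qaly_b, dc, de, icer, label, wtp)


def net_monetary_benefit(cost: float, qaly: float, wtp: float) -> float:
    """NMB = wtp * QALYs - cost (USD)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return qaly * wtp - cost
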