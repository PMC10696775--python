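"""Synthetic fixtures: survival cohorts, digitized curves with risk tables, life tables.

Everything downstream of figure digitization is exercised on data generated
here from known parametric truth, so reconstruction and fitting can be tested
for recovery without any external download.  The default digitization grid
mimics trial reporting cadence (every 3 months out to 48 months).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ipd import DigitizedCurve, IPDRecord, RiskTable, km_estimate
from .markov import LifeTable
from .survival import SurvivalDistribution

__all__ = [
    "SyntheticCohortSpec",
    "simulate_cohort",
    "digitize",
    "make_life_table",
    "default_grid",
]


def default_grid(horizon: float = 48.0, step: float = 3.0) -> np.ndarray:
    return np.arange(step, horizon + step / 2, step, dtype=float)


@dataclass
class SyntheticCohortSpec:
    """Generating truth for a synthetic trial cohort."""

    n: int
    event_dist: SurvivalDistribution
    censor_dist: SurvivalDistribution | None = None
    admin_censor_time: float | None = None  # administrative end of follow-up
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("cohort size must be positive")
        self.metadata.setdefault("seed", self.seed)


def simulate_cohort(spec: SyntheticCohortSpec) -> list[IPDRecord]:
    """Draw event/censoring times; observed time is the minimum of the two."""
    rng = np.random.default_rng(spec.seed)
    t_event = spec.event_dist.rvs(spec.n, rng)
    t_cens = np.full(spec.n, np.inf)
    if spec.censor_dist is not None:
        t_cens = spec.censor_dist.rvs(spec.n, rng)
    if spec.admin_censor_time is not None:
        t_cens = np.minimum(t_cens, spec.admin_censor_time)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    if np.any(time <= 0):
        raise ValueError("simulated follow-up times must be strictly positive")
    return [IPDRecord(float(t), bool(e)) for t, e in zip(time, event)]


def digitize(
    ipd,
    grid_times,
    jitter: float = 0.0,
    seed: int = 0,
) -> tuple[DigitizedCurve, RiskTable]:
    """Emulate figure digitization: KM values at grid times + exact risk counts.

    `jitter` adds bounded uniform coordinate noise (max absolute deviation
    `jitter`) to the survival readings, as a stand-in for digitization error;
    monotonicity and the (0, 1) anchor are preserved.
    """
    rows = list(ipd)
    if not rows:
        raise ValueError("digitize requires a non-empty cohort")
    times = np.array([r.time for r in rows], dtype=float)
    grid = np.asarray(grid_times, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid times must be a non-empty increasing sequence")
    max_t = times.max()
    if grid[-1] > max_t:
        import warnings

        warnings.warn("grid extends beyond follow-up; truncating", stacklevel=2)
        grid = grid[grid <= max_t]

    km = km_estimate(rows)
    s = np.asarray(km.at(grid), dtype=float)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        s = s + rng.uniform(-jitter, jitter, size=s.size)
        s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
    n_at_risk = np.array([(times >= t).sum() for t in grid], dtype=int)
    curve = DigitizedCurve(np.concatenate([[0.0], grid]), np.concatenate([[1.0], s]))
    risk_times = np.concatenate([[0.0], grid])
    risk_n = np.concatenate([[len(rows)], n_at_risk])
    return curve, RiskTable(risk_times, risk_n)


def make_life_table(profile: str = "aging", flat_q: float = 0.02) -> LifeTable:
    """Abridged all-cause mortality for ages 65-100.

    ``aging`` is a Gompertz-Makeham curve q(a) = 0.0008 + 0.0115*exp(0.088*(a-65))
    (strictly increasing, roughly the scale of elderly mortality in Chinese
    census-based life tables); ``flat`` applies one annual probability to all
    ages.  Both are synthetic stand-ins, replaceable through the model config.
    """
    ages = np.arange(65, 101)
    if profile == "flat":
        q = np.full(ages.size, flat_q)
    elif profile == "aging":
        q = np.minimum(0.0008 + 0.0115 * np.exp(0.088 * (ages - 65)), 0.7)
    elif profile == "zero":
        q = np.zeros(ages.size)
    else:
        raise ValueError("profile must be 'flat', 'aging' or 'zero'")
    return LifeTable(ages, q)
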