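"""Pseudo individual-patient-data reconstruction from digitized Kaplan-Meier curves.

Published survival figures report only curve coordinates and a number-at-risk
table.  The interval algorithm implemented here (after Guyot and colleagues)
allocates integer event and censoring counts inside each inter-risk-time
interval so that (a) the product-limit estimate of the reconstructed data
tracks the digitized survival drops and (b) the implied number at risk at the
next risk time matches the published table.  Censoring times are spread
uniformly within an interval; fractional event counts are converted to
integers by largest-remainder rounding so interval totals are preserved.

Two variants are provided: the default uses only the risk table; when the
total number of events is reported, ``reconstruct_ipd(..., total_events=k)``
additionally nudges the final interval so that the overall event count matches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

__all__ = [
    "DigitizedCurve",
    "RiskTable",
    "IPDRecord",
    "ReconstructionError",
    "reconstruct_ipd",
    "km_estimate",
]


class ReconstructionError(ValueError):
    """Inconsistent digitized inputs (rising survival, growing risk set, ...)."""


@dataclass(frozen=True)
class IPDRecord:
    """One reconstructed subject: follow-up time (months) and event flag."""

    time: float
    event: bool

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("IPD times must be strictly positive")


class DigitizedCurve:
    """Ordered (time, survival) coordinates read off a published KM curve."""

    def __init__(self, times, survival):
        t = np.asarray(times, dtype=float)
        s = np.asarray(survival, dtype=float)
        if t.ndim != 1 or t.shape != s.shape or t.size == 0:
            raise ReconstructionError("curve needs matching 1-d time/survival arrays")
        if np.any(np.diff(t) <= 0):
            raise ReconstructionError("curve times must be strictly increasing")
        if np.any(np.diff(s) > 1e-9):
            raise ReconstructionError("digitized survival must be non-increasing")
        if np.any(s < -1e-9) or np.any(s > 1 + 1e-9):
            raise ReconstructionError("survival values must lie in [0, 1]")
        if t[0] > 0:  # anchor at (0, 1)
            t = np.concatenate([[0.0], t])
            s = np.concatenate([[1.0], s])
        self.times = t
        self.survival = np.clip(s, 0.0, 1.0)

    def __len__(self):
        return self.times.size

    def at(self, t) -> np.ndarray:
        """Step-function evaluation (last digitized value at or before t)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return self.survival[np.clip(idx, 0, None)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "survival": self.survival})


class RiskTable:
    """Number of patients at risk at a sequence of follow-up times."""

    def __init__(self, times, n_at_risk):
        t = np.asarray(times, dtype=float)
        n = np.asarray(n_at_risk, dtype=int)
        if t.ndim != 1 or t.shape != n.shape or t.size < 2:
            raise ReconstructionError("risk table needs >= 2 (time, n) entries")
        if np.any(np.diff(t) <= 0):
            raise ReconstructionError("risk-table times must be strictly increasing")
        if np.any(np.diff(n) > 0):
            raise ReconstructionError("numbers at risk must be non-increasing")
        if np.any(n < 0):
            raise ReconstructionError("numbers at risk must be non-negative")
        self.times = t
        self.n_at_risk = n

    def __len__(self):
        return self.times.size


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of `total` across bins proportional to `fractions`."""
    base = np.floor(fractions).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(fractions - np.floor(fractions)))
        base[order[:short]] += 1
    elif short < 0:
        order = np.argsort(fractions - np.floor(fractions))
        for idx in order:
            if short == 0:
                break
            if base[idx] > 0:
                base[idx] -= 1
                short += 1
    return np.maximum(base, 0)


def _interval_pass(
    n_start: int,
    s_prev: float,
    pts: list[tuple[float, float]],
    n_censor: int,
    lo: float,
    hi: float,
):
    """Run one interval with a fixed censoring budget.

    Censorings are spread uniformly over (lo, hi); events at each digitized
    point are the fractional product-limit counts, integerised within the
    interval by largest-remainder rounding.  Returns (events, censorings,
    n_end, s_end) where events/censorings are (time, count) lists.
    """
    cen_times = [lo + (j + 0.5) * (hi - lo) / n_censor for j in range(n_censor)]
    # first fractional pass to get per-point event weights
    frac = []
    n = float(n_start)
    s_run = s_prev
    ci = 0
    for t_k, s_k in pts:
        while ci < n_censor and cen_times[ci] <= t_k:
            n -= 1.0
            ci += 1
        d = 0.0
        if s_run > 0 and n > 0:
            d = max(0.0, min(n, n * (1.0 - s_k / s_run)))
            if d > 0:
                s_run *= (n - d) / n
        frac.append(d)
        n -= d
    frac = np.asarray(frac, dtype=float)
    d_total = int(round(frac.sum()))
    d_int = _largest_remainder(frac, min(d_total, n_start)) if frac.size else frac

    # integer pass
    events, cens = [], []
    n = n_start
    s_run = s_prev
    ci = 0
    for (t_k, s_k), d in zip(pts, d_int):
        while ci < n_censor and cen_times[ci] <= t_k:
            cens.append((cen_times[ci], 1))
            n -= 1
            ci += 1
        d = int(min(d, max(n, 0)))
        if d > 0:
            s_run *= (n - d) / n
            events.append((t_k, d))
            n -= d
    while ci < n_censor and n > 0:
        cens.append((cen_times[ci], 1))
        n -= 1
        ci += 1
    return events, cens, n, s_run


def reconstruct_ipd(
    curve: DigitizedCurve,
    risk: RiskTable,
    total_events: int | None = None,
) -> list[IPDRecord]:
    """Reconstruct approximate IPD from a digitized curve and its risk table.

    The number of subjects equals the initial number at risk; within every
    interval the event + censoring count equals the published drop in the risk
    set, and the reconstructed product-limit curve matches the digitized
    survival at the digitized time points (up to integer rounding).
    """
    if not isinstance(curve, DigitizedCurve):
        curve = DigitizedCurve(*curve)
    if not isinstance(risk, RiskTable):
        risk = RiskTable(*risk)
    if curve.times[-1] < risk.times[-2]:
        raise ReconstructionError("curve must span the risk-table time range")

    records: list[IPDRecord] = []
    s_prev = 1.0
    n = int(risk.n_at_risk[0])
    bounds = list(risk.times) + [max(curve.times[-1], risk.times[-1]) + 1e-9]
    targets = list(risk.n_at_risk[1:]) + [None]

    for i in range(len(risk)):
        lo, hi = bounds[i], bounds[i + 1]
        mask = (curve.times > lo) & (curve.times <= hi)
        if i == 0:
            mask |= (curve.times > 0) & (curve.times <= hi)
        pts = list(zip(curve.times[mask], curve.survival[mask]))
        target = targets[i]

        if target is None:
            # final interval: risk-table-only variant assumes no censoring
            # before the last digitized point; survivors censored at the end.
            events, cens, n_end, s_end = _interval_pass(n, s_prev, pts, 0, lo, hi)
            for t, d in events:
                records.extend(IPDRecord(t, True) for _ in range(d))
            last_t = curve.times[-1] if len(curve.times) else hi
            records.extend(IPDRecord(max(last_t, lo + 1e-9), False) for _ in range(n_end))
            n, s_prev = 0, s_end
            break

        c_hat = 0
        seen = set()
        for _ in range(60):
            events, cens, n_end, s_end = _interval_pass(n, s_prev, pts, c_hat, lo, hi)
            gap = n_end - target
            if gap == 0:
                break
            c_new = int(np.clip(c_hat + gap, 0, n))
            if c_new == c_hat or c_new in seen:
                break
            seen.add(c_hat)
            c_hat = c_new
        # force exact conservation with trailing censorings
        if n_end > target:
            cens = cens + [(hi - 1e-9 if np.isfinite(hi) else lo + 1e-9, 1)] * (
                n_end - target
            )
            n_end = target
        for t, d in events:
            records.extend(IPDRecord(t, True) for _ in range(d))
        for t, c in cens:
            records.extend(IPDRecord(t, False) for _ in range(c))
        n, s_prev = n_end, s_end

    if total_events is not None:
        records = _match_total_events(records, int(total_events))
    return sorted(records, key=lambda r: (r.time, not r.event))


def _match_total_events(records: list[IPDRecord], total: int) -> list[IPDRecord]:
    """Flip the latest censorings/events so the overall event count matches."""
    d = sum(r.event for r in records)
    out = sorted(records, key=lambda r: r.time)
    if d < total:
        need = total - d
        for i in range(len(out) - 1, -1, -1):
            if need == 0:
                break
            if not out[i].event:
                out[i] = IPDRecord(out[i].time, True)
                need -= 1
    elif d > total:
        need = d - total
        for i in range(len(out) - 1, -1, -1):
            if need == 0:
                break
            if out[i].event:
                out[i] = IPDRecord(out[i].time, False)
                need -= 1
    return out


def km_estimate(ipd) -> DigitizedCurve:
    """Product-limit (Kaplan-Meier) estimate of a reconstructed cohort."""
    rows = list(ipd)
    if not rows:
        raise ValueError("km_estimate requires a non-empty cohort")
    times = np.array([r.time for r in rows], dtype=float)
    events = np.array([r.event for r in rows], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    if t[0] != 0.0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    return DigitizedCurve(t, s)
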