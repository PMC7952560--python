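"""Growth-rate computation from OD600 time courses.

The growth-rate statistic is the log ratio of optical densities over a
fixed interval, ``rate = ln(OD(t1) / OD(t0)) / (t1 - t0)`` in h^-1, with
the default interval 4 h -> 16 h (divisor 12).  Replicates are handled by
computing per-replicate rates and summarising afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

__all__ = ["GrowthCurve", "growth_rate", "summarize_rates", "welch_ttest"]


@dataclass(frozen=True)
class GrowthCurve:
    """One replicate's OD600 time course (times in hours, strictly increasing)."""

    times: tuple[float, ...]
    od: tuple[float, ...]
    replicate: str = ""

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        od = tuple(float(x) for x in self.od)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if len(times) != len(od):
            raise ValueError("times and od must have equal length")
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(x < 0 for x in od):
            raise ValueError("OD readings must be non-negative")

    def od_at(self, t: float) -> float:
        for ti, xi in zip(self.times, self.od):
            if math.isclose(ti, t, rel_tol=0.0, abs_tol=1e-9):
                return xi
        raise ValueError(
            f"no OD reading at t={t} h (interpolation is refused by design)"
        )


def growth_rate(curve: GrowthCurve, t0: float = 4.0, t1: float = 16.0) -> float:
    """``ln(OD(t1)/OD(t0)) / (t1 - t0)`` in h^-1; default 4 -> 16 h.

    Both time points must be present in the curve (no interpolation) and
    both readings positive.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    od0, od1 = curve.od_at(t0), curve.od_at(t1)
    if od0 <= 0 or od1 <= 0:
        raise ValueError("OD must be positive at both endpoints")
    return math.log(od1 / od0) / (t1 - t0)


def summarize_rates(
    curves: list[GrowthCurve], t0: float = 4.0, t1: float = 16.0
) -> tuple[float, float]:
    """Mean and sample SD of per-replicate growth rates."""
    rates = [growth_rate(c, t0, t1) for c in curves]
    return float(np.mean(rates)), float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0


def welch_ttest(a, b):
    """Welch two-sample t-test (plumbing, not method): thin wrapper around
    ``scipy.stats.ttest_ind(equal_var=False)``; returns (t, p)."""
    res = _stats.ttest_ind(np.asarray(a), np.asarray(b), equal_var=False)
    return float(res.statistic), float(res.pvalue)
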