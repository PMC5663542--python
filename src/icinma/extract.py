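"""Recover relative-effect summaries that trials did not report directly.

Survival: log hazard ratios reconstructed from log-rank p-values and event
counts, or point HRs from median survival times under an exponential-survival
approximation.  Safety: log odds ratios from per-arm adverse-event counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "SurvivalSummary",
    "TwoByTwo",
    "hr_from_logrank",
    "hr_from_medians",
    "or_from_counts",
]


@dataclass(frozen=True)
class SurvivalSummary:
    events_total: int
    p_logrank: float
    allocation_ratio: float = 1.0
    median1: float | None = None
    median2: float | None = None

    def __post_init__(self):
        if self.events_total < 0:
            raise ValueError("events_total must be non-negative")
        if not 0 < self.p_logrank <= 1:
            raise ValueError("p_logrank must be in (0, 1]")
        for m in (self.median1, self.median2):
            if m is not None and m <= 0:
                raise ValueError("medians must be positive")


@dataclass(frozen=True)
class TwoByTwo:
    events1: int
    n1: int
    events2: int
    n2: int

    def __post_init__(self):
        for e, n in ((self.events1, self.n1), (self.events2, self.n2)):
            if n <= 0 or not 0 <= e <= n:
                raise ValueError(f"invalid 2x2 cell: {e}/{n}")


def hr_from_logrank(
    events_total: int,
    p_two_sided: float,
    allocation_ratio: float = 1.0,
    sign: float = -1.0,
) -> tuple[float, float]:
    """Log HR and its se from a two-sided log-rank p-value and total events.

    The log-rank variance is approximated by V = E * R/(1+R)^2 with E the
    total events and R the allocation ratio; the observed-minus-expected
    statistic is recovered from the normal quantile of the p-value, and
    y = (O-E)/V, se = 1/sqrt(V).  The direction of effect cannot be recovered
    from a two-sided p, so the caller supplies ``sign`` (-1: first arm
    favoured).
    """
    if events_total <= 0:
        raise ValueError("events_total must be positive")
    if not 0 < p_two_sided < 1:
        raise ValueError("p must lie strictly in (0, 1)")
    if allocation_ratio <= 0:
        raise ValueError("allocation_ratio must be positive")
    r = allocation_ratio
    v = events_total * r / (1.0 + r) ** 2
    z = norm.isf(p_two_sided / 2.0)
    o_minus_e = math.copysign(1.0, sign) * z * math.sqrt(v)
    return o_minus_e / v, 1.0 / math.sqrt(v)


def hr_from_medians(median_trt: float, median_ctrl: float) -> float:
    """Point HR (treatment vs control) from median survival times.

    Under exponential survival the hazard is log(2)/median, so
    HR = median_ctrl / median_trt.  No standard error is recoverable; the
    result is a point estimate only and must not enter a likelihood unless
    the caller attaches an se.
    """
    if median_trt <= 0 or median_ctrl <= 0:
        raise ValueError("medians must be positive")
    return median_ctrl / median_trt


def or_from_counts(
    t: TwoByTwo, correction: float | None = 0.5
) -> tuple[float, float]:
    """Log odds ratio (arm1 vs arm2) and its se from per-arm event counts.

    A continuity constant (default 0.5, Haldane-Anscombe) is added to all four
    cells only when a zero cell exists; ``correction=None`` disables it, in
    which case zero cells are rejected.
    """
    a, b = t.events1, t.n1 - t.events1
    c, d = t.events2, t.n2 - t.events2
    if min(a, b, c, d) == 0:
        if correction is None:
            raise ValueError(
                "zero cell in 2x2 table and continuity correction disabled"
            )
        a, b, c, d = (x + correction for x in (a, b, c, d))
    y = math.log(a * d / (b * c))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return y, se
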