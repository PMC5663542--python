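"""Convergence and small-study/publication-bias diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FunnelPoint", "gelman_rubin", "funnel_points"]


@dataclass(frozen=True)
class FunnelPoint:
    trial_id: str
    comparison: tuple[str, str]
    centered: float  # observed log effect minus its comparison's direct pool
    se: float


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor per parameter.

    ``chains`` has shape (n_chains, n_draws) or (n_chains, n_draws, n_params).
    PSRF = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain variance
    and B the between-chain variance of the chain means (times n).  Constant
    identical chains (W = 0) are reported as 1 by convention.
    """
    x = np.asarray(chains, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[:, :, None]
    if x.ndim != 3:
        raise ValueError("chains must be (n_chains, n_draws[, n_params])")
    m, n = x.shape[0], x.shape[1]
    if m < 2:
        raise ValueError("at least two chains are required")
    if n < 2:
        raise ValueError("at least two draws per chain are required")
    w = x.var(axis=1, ddof=1).mean(axis=0)  # (P,)
    b_over_n = x.mean(axis=1).var(axis=0, ddof=1)  # B/n
    psrf = np.ones_like(w)
    ok = w > 0
    v_hat = (n - 1) / n * w[ok] + b_over_n[ok]
    psrf[ok] = np.sqrt(v_hat / w[ok])
    return float(psrf[0]) if squeeze else psrf


def funnel_points(network, directs) -> list[FunnelPoint]:
    """Comparison-adjusted funnel points for every survival contrast.

    Each observed contrast is centered on the fixed-effect direct pooled
    estimate of its own comparison (oriented the same way), so points from
    different comparisons share a common zero; a single-study comparison sits
    exactly at zero.  ``directs`` maps or lists the pairwise fixed-effect
    results (see :mod:`icinma.pairwise`).
    """
    pool = {res.comparison: res.y for res in directs}
    points = []
    for c in network.contrasts:
        pair = (c.comparator, c.baseline)  # pairwise convention
        if pair in pool:
            key, y_oriented = pair, c.y
        elif pair[::-1] in pool:
            key, y_oriented = pair[::-1], -c.y
        else:
            raise ValueError(
                f"no direct pooled estimate for comparison {pair} "
                f"(trial {c.trial_id})"
            )
        points.append(
            FunnelPoint(
                trial_id=c.trial_id,
                comparison=key,
                centered=y_oriented - pool[key],
                se=c.se,
            )
        )
    return points
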