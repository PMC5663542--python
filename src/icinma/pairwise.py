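"""Traditional pairwise meta-analysis and the direct-vs-network consistency check.

Fixed-effect pooling is inverse-variance; random-effects pooling uses the
DerSimonian-Laird moment estimate of the between-trial variance.  Severe
heterogeneity is flagged at I^2 > 50% or a chi-square p-value < 0.10.
Consistency of the network is assessed, comparison by comparison, as interval
overlap between the direct pooled estimate and the network credible interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import chi2, norm

from .data import EvidenceNetwork
from .model import LeagueTable

__all__ = [
    "PairwiseResult",
    "ConsistencyRow",
    "pool_fixed",
    "pool_random",
    "heterogeneity",
    "direct_effects",
    "consistency_table",
]

I2_SEVERE = 50.0
P_SEVERE = 0.10


@dataclass
class PairwiseResult:
    comparison: tuple[str, str]  # (comparator, baseline): y is comparator vs baseline
    method: str  # fixed_iv | random_dl
    y: float
    se: float
    ci_low: float  # log scale
    ci_high: float
    q: float = 0.0
    df: int = 0
    p_q: float = 1.0
    i2: float = 0.0
    tau2: float = 0.0
    n_studies: int = 1
    severe_heterogeneity: bool = False

    @property
    def ratio(self) -> float:
        return math.exp(self.y)

    @property
    def ratio_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


@dataclass
class ConsistencyRow:
    comparison: tuple[str, str]
    direct: float  # ratio scale
    direct_ci: tuple[float, float]
    network: float
    network_cri: tuple[float, float]
    overlap: bool
    log_difference: float


_Z95 = float(norm.ppf(0.975))


def _check(effects) -> list[tuple[float, float]]:
    effects = [(float(y), float(se)) for y, se in effects]
    if not effects:
        raise ValueError("no effects to pool")
    if any(se <= 0 for _, se in effects):
        raise ValueError("standard errors must be positive")
    return effects


def pool_fixed(
    effects, comparison: tuple[str, str] = ("", "")
) -> PairwiseResult:
    """Inverse-variance fixed-effect pool of (log effect, se) pairs."""
    effects = _check(effects)
    w = [1.0 / se**2 for _, se in effects]
    sw = sum(w)
    y = sum(wi * yi for wi, (yi, _) in zip(w, effects)) / sw
    se = sw**-0.5
    res = PairwiseResult(
        comparison=comparison,
        method="fixed_iv",
        y=y,
        se=se,
        ci_low=y - _Z95 * se,
        ci_high=y + _Z95 * se,
        n_studies=len(effects),
    )
    if len(effects) >= 2:
        res.q, res.df, res.p_q, res.i2, res.tau2 = heterogeneity(effects)
        res.severe_heterogeneity = res.i2 > I2_SEVERE or res.p_q < P_SEVERE
    return res


def heterogeneity(effects) -> tuple[float, int, float, float, float]:
    """Cochran's Q, its df and p-value, I^2 (%), and the DerSimonian-Laird
    moment estimate of the between-trial variance tau^2."""
    effects = _check(effects)
    if len(effects) < 2:
        raise ValueError("heterogeneity needs at least two effects")
    w = [1.0 / se**2 for _, se in effects]
    sw = sum(w)
    pooled = sum(wi * yi for wi, (yi, _) in zip(w, effects)) / sw
    q = sum(wi * (yi - pooled) ** 2 for wi, (yi, _) in zip(w, effects))
    df = len(effects) - 1
    p_q = float(chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    denom = sw - sum(wi**2 for wi in w) / sw
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return q, df, p_q, i2, tau2


def pool_random(
    effects, comparison: tuple[str, str] = ("", "")
) -> PairwiseResult:
    """DerSimonian-Laird random-effects pool: inverse-variance weights with
    tau^2 added to every within-study variance."""
    effects = _check(effects)
    if len(effects) < 2:
        raise ValueError("random-effects pooling needs at least two effects")
    q, df, p_q, i2, tau2 = heterogeneity(effects)
    w = [1.0 / (se**2 + tau2) for _, se in effects]
    sw = sum(w)
    y = sum(wi * yi for wi, (yi, _) in zip(w, effects)) / sw
    se = sw**-0.5
    return PairwiseResult(
        comparison=comparison,
        method="random_dl",
        y=y,
        se=se,
        ci_low=y - _Z95 * se,
        ci_high=y + _Z95 * se,
        q=q,
        df=df,
        p_q=p_q,
        i2=i2,
        tau2=tau2,
        n_studies=len(effects),
        severe_heterogeneity=i2 > I2_SEVERE or p_q < P_SEVERE,
    )


def direct_effects(
    network: EvidenceNetwork, outcome: str = "PFS"
) -> dict[tuple[str, str], list[tuple[float, float]]]:
    """Group the observed contrasts by comparison, canonically oriented.

    The canonical orientation of a pair follows the treatment registry order
    (later node vs earlier node); a trial whose contrast is stored the other
    way round enters with its sign flipped.  Each trial contributes its
    baseline-anchored contrast once per pair, so multi-arm trials are not
    double-counted within a comparison.
    """
    order = {t: i for i, t in enumerate(network.treatments)}
    groups: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for c in network.contrasts_for(outcome):
        b, k = c.baseline, c.comparator
        if order[b] < order[k]:
            pair, y = (k, b), c.y
        else:
            pair, y = (b, k), -c.y
        groups.setdefault(pair, []).append((y, c.se))
    return groups


def pairwise_results(
    network: EvidenceNetwork, outcome: str = "PFS"
) -> list[PairwiseResult]:
    """Fixed-effect pool per direct comparison (random-effects where >= 2
    studies exist), in registry order."""
    out = []
    for pair, effects in direct_effects(network, outcome).items():
        out.append(pool_fixed(effects, comparison=pair))
        if len(effects) >= 2:
            out.append(pool_random(effects, comparison=pair))
    return out


def consistency_table(
    network_result: LeagueTable, directs: list[PairwiseResult]
) -> list[ConsistencyRow]:
    """Direct vs network comparison, one row per directly-informed pair.

    The network entry is oriented to match the direct comparison
    (comparator-vs-baseline); the overlap flag is true iff the direct CI and
    the network credible interval intersect.
    """
    rows = []
    for res in directs:
        if res.method != "fixed_iv":
            continue
        comp, base = res.comparison
        if comp not in network_result.treatments or base not in network_result.treatments:
            raise ValueError(
                f"comparison {res.comparison} absent from the league table"
            )
        net_med, net_lo, net_hi = network_result.entry(comp, base)
        d_lo, d_hi = res.ratio_ci
        rows.append(
            ConsistencyRow(
                comparison=res.comparison,
                direct=res.ratio,
                direct_ci=(d_lo, d_hi),
                network=net_med,
                network_cri=(net_lo, net_hi),
                overlap=(d_lo <= net_hi) and (net_lo <= d_hi),
                log_difference=res.y - math.log(net_med),
            )
        )
    return rows
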