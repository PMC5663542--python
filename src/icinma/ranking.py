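"""Treatment rankings from posterior draws: rankograms and cumulative scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PosteriorDraws

__all__ = ["RankMatrix", "rank_probabilities", "cumulative_rank_score"]


@dataclass
class RankMatrix:
    """P[t, j] = probability that treatment t has rank j+1 (rank 1 = best).

    Doubly stochastic: every row and column sums to 1.
    """

    treatments: list[str]
    probs: np.ndarray
    direction: str  # lower_better | higher_better

    def prob(self, treatment: str, rank: int) -> float:
        """Probability of holding the given 1-based rank."""
        return float(self.probs[self.treatments.index(treatment), rank - 1])

    def best(self) -> str:
        """Treatment with the highest probability of rank 1."""
        return self.treatments[int(np.argmax(self.probs[:, 0]))]


def rank_probabilities(
    draws: PosteriorDraws,
    direction: str = "lower_better",
    include: list[str] | None = None,
    tie_seed: int = 0,
) -> RankMatrix:
    """Empirical rank distribution of the included treatments.

    Per draw, treatments are ordered by their basic-parameter value under the
    outcome's direction (for hazard/odds outcomes lower is better).  Exact
    ties — measure-zero for continuous posteriors, but possible in degenerate
    inputs — are broken by a uniform random permutation from a dedicated
    seeded generator.  Defaults to the reportable treatments, so auxiliary
    likelihood-only nodes stay out of the ranking.
    """
    if direction not in ("lower_better", "higher_better"):
        raise ValueError(f"unknown direction {direction!r}")
    names, mat = draws.basic_draws(include_reference=True)
    if include is None:
        include = [t for t in names if t in draws.design.reportable]
    if not include:
        raise ValueError("empty treatment set for ranking")
    cols = [names.index(t) for t in include]
    vals = mat[:, cols]
    if direction == "higher_better":
        vals = -vals
    n_draws, T = vals.shape
    rng = np.random.default_rng(tie_seed)
    tie_keys = rng.random(vals.shape)
    counts = np.zeros((T, T), dtype=np.int64)
    ranks = np.empty(T, dtype=np.intp)
    rows = np.arange(T)
    for i in range(n_draws):
        order = np.lexsort((tie_keys[i], vals[i]))
        ranks[order] = rows
        counts[rows, ranks] += 1
    return RankMatrix(
        treatments=list(include),
        probs=counts / float(n_draws),
        direction=direction,
    )


def cumulative_rank_score(P: RankMatrix) -> dict[str, float]:
    """SUCRA-style summary: mean cumulative rank probability over ranks
    1..T-1.  1 means always best, 0 always worst; a uniform rank
    distribution scores 0.5."""
    probs = P.probs
    T = probs.shape[0]
    if T == 1:
        return {P.treatments[0]: 1.0}
    cum = np.cumsum(probs, axis=1)[:, : T - 1]
    scores = cum.mean(axis=1)
    return {t: float(s) for t, s in zip(P.treatments, scores)}
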