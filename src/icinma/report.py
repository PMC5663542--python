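"""Full-analysis orchestration: one config in, a directory of report files out.

``run_analysis`` ingests the evidence table, fits the fixed- and
random-effects models, selects the reporting model by DIC (ties within 3
units favour fixed), and writes the league table, rank matrix, pairwise and
consistency tables, funnel points and convergence diagnostics as delimited
text, plus a structured run manifest.  Outputs are deterministic given the
config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .data import (
    EvidenceNetwork,
    filter_low_risk,
    load_risk_flags,
    load_trial_table,
    merge_dose_arms,
    resolve_auxiliary_nodes,
)
from .diagnostics import funnel_points
from .model import (
    LeagueTable,
    McmcConfig,
    ModelSpec,
    league_table,
    sample_posterior,
)
from .pairwise import consistency_table, pairwise_results
from .ranking import cumulative_rank_score, rank_probabilities

__all__ = ["RunConfig", "run_analysis", "render_league"]

log = logging.getLogger(__name__)

DIC_TIE_MARGIN = 3.0


@dataclass
class RunConfig:
    trial_table: str | None = None  # None: shipped melanoma table
    risk_flags: str | None = None
    outcome: str = "PFS"
    dose_policy: str = "pool"
    aux_policy: str = "aux_node"
    reference: str = "CHE"
    prior_sd_d: float = 15.0
    prior_tau_upper: float = 2.0
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    out_dir: str = "results/run"
    direction: str = "lower_better"
    sensitivity: bool = False
    reports: tuple[str, ...] = (
        "league", "ranks", "pairwise", "consistency", "funnel", "diagnostics",
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        mcmc = McmcConfig(**raw.pop("mcmc", {}))
        return cls(mcmc=mcmc, **raw)

    def effective(self) -> dict:
        d = asdict(self)
        d["reports"] = list(self.reports)
        return d


def _load_network(config: RunConfig) -> EvidenceNetwork:
    if config.trial_table is None:
        net = load_trial_table(datasets.trial_table_path(), schema=config.outcome)
    else:
        net = load_trial_table(config.trial_table, schema=config.outcome)
    net = merge_dose_arms(net, policy=config.dose_policy)
    return resolve_auxiliary_nodes(net, policy=config.aux_policy)


def render_league(table: LeagueTable, path: str | Path) -> None:
    """Write the league table as delimited text in the column-vs-row
    orientation (ratios below 1 favour the column treatment), ratios to two
    decimals with 95% credible intervals, a dash on the diagonal, and a
    significance flag column per cell pair.  Byte-stable for a given table."""
    treatments = table.treatments
    lines = ["row_treatment," + ",".join(treatments)]
    for i, row_t in enumerate(treatments):
        cells = [row_t]
        for j, col_t in enumerate(treatments):
            if i == j:
                cells.append("-")
                continue
            med, lo, hi = table.entry(col_t, row_t)
            mark = "*" if table.significant(col_t, row_t) else ""
            cells.append(f"{med:.2f} ({lo:.2f}-{hi:.2f}){mark}")
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def _league_long(table: LeagueTable) -> pd.DataFrame:
    rows = []
    for col_t in table.treatments:
        for row_t in table.treatments:
            if col_t == row_t:
                continue
            med, lo, hi = table.entry(col_t, row_t)
            rows.append(
                {
                    "column": col_t,
                    "row": row_t,
                    "ratio": med,
                    "cri_low": lo,
                    "cri_high": hi,
                    "significant": table.significant(col_t, row_t),
                }
            )
    return pd.DataFrame(rows)


def run_analysis(config: RunConfig) -> dict:
    """Run the configured analysis end to end; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(str(path))

    network = _load_network(config)
    fits = {}
    for effect_model in ("fixed", "random"):
        spec = ModelSpec(
            effect_model=effect_model,
            outcome=config.outcome,
            reference=config.reference,
            prior_sd_d=config.prior_sd_d,
            prior_tau_upper=config.prior_tau_upper,
        )
        draws, diag = sample_posterior(network, spec, config.mcmc)
        fits[effect_model] = (spec, draws, diag)
        log.info(
            "%s model: DIC %.2f (pD %.2f), max PSRF %.3f",
            effect_model, diag.dic, diag.pd, diag.max_psrf,
        )

    chosen = (
        "fixed"
        if fits["fixed"][2].dic <= fits["random"][2].dic + DIC_TIE_MARGIN
        else "random"
    )
    spec, draws, diag = fits[chosen]
    converged = all(f[2].converged for f in fits.values())

    directs = pairwise_results(network, config.outcome)
    fixed_directs = [r for r in directs if r.method == "fixed_iv"]

    if "league" in config.reports:
        emit("league_table.csv", lambda p: render_league(league_table(draws), p))
        emit(
            "league_long.csv",
            lambda p: _league_long(league_table(draws)).to_csv(p, index=False),
        )

    if "ranks" in config.reports:
        ranks = rank_probabilities(draws, direction=config.direction)
        sucra = cumulative_rank_score(ranks)
        def _write_ranks(p):
            rows = [
                {
                    "treatment": t,
                    "rank": j + 1,
                    "probability": float(ranks.probs[i, j]),
                }
                for i, t in enumerate(ranks.treatments)
                for j in range(len(ranks.treatments))
            ]
            pd.DataFrame(rows).to_csv(p, index=False)
        emit("rank_matrix.csv", _write_ranks)
        emit(
            "rank_scores.csv",
            lambda p: pd.DataFrame(
                [{"treatment": t, "score": s} for t, s in sucra.items()]
            ).to_csv(p, index=False),
        )

    if "pairwise" in config.reports:
        def _write_pairwise(p):
            pd.DataFrame(
                [
                    {
                        "comparator": r.comparison[0],
                        "baseline": r.comparison[1],
                        "method": r.method,
                        "ratio": r.ratio,
                        "ci_low": r.ratio_ci[0],
                        "ci_high": r.ratio_ci[1],
                        "q": r.q,
                        "df": r.df,
                        "p_q": r.p_q,
                        "i2": r.i2,
                        "tau2_dl": r.tau2,
                        "n_studies": r.n_studies,
                        "severe_heterogeneity": r.severe_heterogeneity,
                    }
                    for r in directs
                ]
            ).to_csv(p, index=False)
        emit("pairwise.csv", _write_pairwise)

    if "consistency" in config.reports:
        full = league_table(draws, include=draws.design.nodes)
        rows = consistency_table(full, fixed_directs)
        def _write_cons(p):
            pd.DataFrame(
                [
                    {
                        "comparator": r.comparison[0],
                        "baseline": r.comparison[1],
                        "direct": r.direct,
                        "direct_low": r.direct_ci[0],
                        "direct_high": r.direct_ci[1],
                        "network": r.network,
                        "network_low": r.network_cri[0],
                        "network_high": r.network_cri[1],
                        "overlap": r.overlap,
                        "log_difference": r.log_difference,
                    }
                    for r in rows
                ]
            ).to_csv(p, index=False)
        emit("consistency.csv", _write_cons)

    if "funnel" in config.reports:
        points = funnel_points(network, fixed_directs)
        emit(
            "funnel.csv",
            lambda p: pd.DataFrame(
                [
                    {
                        "trial_id": fp.trial_id,
                        "comparator": fp.comparison[0],
                        "baseline": fp.comparison[1],
                        "centered_log_effect": fp.centered,
                        "se": fp.se,
                    }
                    for fp in points
                ]
            ).to_csv(p, index=False),
        )

    if "diagnostics" in config.reports:
        def _write_diag(p):
            rows = []
            for name, (s, dr, dg) in fits.items():
                for pname, v in dg.psrf.items():
                    rows.append(
                        {
                            "model": name,
                            "parameter": pname,
                            "psrf": v,
                            "dic": dg.dic,
                            "pd": dg.pd,
                            "dbar": dg.dbar,
                        }
                    )
            pd.DataFrame(rows).to_csv(p, index=False)
        emit("convergence.csv", _write_diag)

    sensitivity_info = None
    if config.sensitivity:
        flags_path = config.risk_flags or datasets.risk_flags_path()
        flags = load_risk_flags(flags_path)
        low_risk_net = filter_low_risk(network, flags)
        sdraws, sdiag = sample_posterior(low_risk_net, spec, config.mcmc)
        emit(
            "league_table_low_risk.csv",
            lambda p: render_league(league_table(sdraws), p),
        )
        sensitivity_info = {
            "n_trials": len(low_risk_net.trial_ids),
            "dic": sdiag.dic,
            "converged": sdiag.converged,
        }

    manifest = {
        "chosen_model": chosen,
        "dic": {m: fits[m][2].dic for m in fits},
        "pd": {m: fits[m][2].pd for m in fits},
        "max_psrf": {m: fits[m][2].max_psrf for m in fits},
        "converged": converged,
        "seed": config.mcmc.seed,
        "n_trials": len(network.trial_ids),
        "n_contrasts": len(network.contrasts_for(config.outcome)),
        "files": written,
        "sensitivity": sensitivity_info,
        "config": config.effective(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "run_log.yaml").write_text(
        yaml.safe_dump({"effective_config": config.effective()}, sort_keys=False)
    )
    return manifest
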