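"""Synthetic evidence networks with known truth.

The generator emulates the statistical structure the models assume: observed
log-effect contrasts drawn around true basic parameters with per-trial
standard errors and optional between-trial heterogeneity (with the 0.5 tau^2
within-trial covariance for multi-arm trials), and per-arm binomial
adverse-event counts around treatment-specific log-odds.  Every stage of the
pipeline can therefore be exercised and calibrated without external data.

One root seed spawns independent per-replicate child streams through
``numpy.random.SeedSequence``, so any replicate can be reproduced on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import ContrastObservation, EvidenceNetwork, Treatment, TrialArm
from .model import McmcConfig, ModelSpec, league_table, sample_posterior

__all__ = [
    "TrialLayout",
    "SimTruth",
    "default_truth",
    "default_ae_truth",
    "simulate_contrast_network",
    "simulate_ae_network",
    "recovery_report",
]


@dataclass(frozen=True)
class TrialLayout:
    """One simulated trial: a baseline arm and one contrast per comparator.

    ``se`` (one per comparator) drives the contrast generator; ``arm_n``
    (baseline + comparators) drives the adverse-event generator.
    """

    trial_id: str
    baseline: str
    comparators: tuple[str, ...]
    se: tuple[float, ...] = ()
    arm_n: tuple[int, ...] = ()


@dataclass(frozen=True)
class SimTruth:
    treatments: tuple[str, ...]
    d_true: dict[str, float]  # log scale, reference entry 0
    tau_true: float
    trials: tuple[TrialLayout, ...]
    seed: int = 0
    reference: str = ""
    mu_mean: float = -1.5  # baseline adverse-event log-odds (arm model)
    mu_sd: float = 0.4
    outcome: str = "PFS"

    def __post_init__(self):
        if self.tau_true < 0:
            raise ValueError("tau_true must be non-negative")
        for t in self.trials:
            if t.se and any(s <= 0 for s in t.se):
                raise ValueError(f"trial {t.trial_id}: se must be positive")

    def registry(self) -> dict[str, Treatment]:
        return {t: Treatment(t, t) for t in self.treatments}

    def ref(self) -> str:
        return self.reference or self.treatments[0]


def default_truth(
    tau_true: float = 0.0, seed: int = 0, se: float = 0.15
) -> SimTruth:
    """Hub-and-spoke network with one three-arm loop, mirroring the melanoma
    geometry: reference A at the hub, spokes to B/C/D (the B spoke replicated,
    as repeated comparisons are in the real network), and a three-arm trial
    closing a loop through B and C."""
    trials = (
        TrialLayout("t1", "A", ("B",), se=(se,), arm_n=(200, 200)),
        TrialLayout("t2", "A", ("C",), se=(se,), arm_n=(200, 200)),
        TrialLayout("t3", "A", ("D",), se=(se,), arm_n=(200, 200)),
        TrialLayout("t4", "A", ("B", "C"), se=(se, se), arm_n=(200, 200, 200)),
        TrialLayout("t5", "A", ("B",), se=(se,), arm_n=(200, 200)),
    )
    d_true = {"A": 0.0, "B": -0.7, "C": -0.4, "D": -0.2}
    return SimTruth(
        treatments=("A", "B", "C", "D"),
        d_true=d_true,
        tau_true=tau_true,
        trials=trials,
        seed=seed,
        reference="A",
    )


def default_ae_truth(tau_true: float = 0.0, seed: int = 0) -> SimTruth:
    """Null adverse-event truth (no treatment effect) on the default
    geometry: the calibration condition, where every credible interval
    should cover an odds ratio of 1 at the nominal rate."""
    truth = default_truth(tau_true=tau_true, seed=seed)
    d_true = {"A": 0.0, "B": 0.0, "C": 0.0, "D": 0.0}
    return SimTruth(
        treatments=truth.treatments,
        d_true=d_true,
        tau_true=tau_true,
        trials=truth.trials,
        seed=seed,
        reference="A",
    )


def _contrast_means(truth: SimTruth, layout: TrialLayout) -> np.ndarray:
    d = truth.d_true
    return np.array([d[k] - d[layout.baseline] for k in layout.comparators])


def _draw_trial_effects(
    m: np.ndarray, tau: float, rng: np.random.Generator
) -> np.ndarray:
    """delta ~ MVN(m, Sigma) with Var tau^2, Cov 0.5 tau^2 (multi-arm)."""
    k = m.size
    if tau == 0.0:
        return m.copy()
    cov = 0.5 * tau**2 * (np.eye(k) + np.ones((k, k)))
    return rng.multivariate_normal(m, cov)


def simulate_contrast_network(truth: SimTruth) -> tuple[EvidenceNetwork, SimTruth]:
    """Draw observed log-effect contrasts around the true basic parameters.

    Per trial: delta ~ Normal(d-contrast, tau^2) (0.5 tau^2 correlated within
    multi-arm trials), then y ~ Normal(delta, se^2).  Deterministic given
    ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    arms, contrasts = [], []
    for layout in truth.trials:
        if not layout.se:
            raise ValueError(f"trial {layout.trial_id}: no contrast se given")
        ns = layout.arm_n or (200,) * (1 + len(layout.comparators))
        arms.append(TrialArm(layout.trial_id, layout.baseline, ns[0]))
        m = _contrast_means(truth, layout)
        delta = _draw_trial_effects(m, truth.tau_true, rng)
        for j, (k, se) in enumerate(zip(layout.comparators, layout.se)):
            arms.append(TrialArm(layout.trial_id, k, ns[j + 1]))
            contrasts.append(
                ContrastObservation(
                    trial_id=layout.trial_id,
                    baseline=layout.baseline,
                    comparator=k,
                    outcome=truth.outcome,
                    y=float(delta[j] + se * rng.standard_normal()),
                    se=se,
                )
            )
    net = EvidenceNetwork(truth.registry(), arms, contrasts).validate()
    net.require_connected(truth.outcome)
    return net, truth


def simulate_ae_network(truth: SimTruth) -> tuple[EvidenceNetwork, SimTruth]:
    """Draw per-arm binomial adverse-event counts.

    r_ik ~ Binomial(n_ik, expit(mu_i + delta_ik)), baseline log-odds
    mu_i ~ Normal(mu_mean, mu_sd^2); deterministic given ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    arms = []
    for layout in truth.trials:
        if not layout.arm_n:
            raise ValueError(f"trial {layout.trial_id}: no arm sizes given")
        mu = rng.normal(truth.mu_mean, truth.mu_sd)
        m = _contrast_means(truth, layout)
        delta = _draw_trial_effects(m, truth.tau_true, rng)
        eta = np.concatenate([[mu], mu + delta])
        for tid, n, e in zip(
            (layout.baseline, *layout.comparators), layout.arm_n, eta
        ):
            r = int(rng.binomial(n, expit(e)))
            arms.append(
                TrialArm(layout.trial_id, tid, n, ae_any=r, ae_high=r)
            )
    net = EvidenceNetwork(truth.registry(), arms, []).validate()
    return net, truth


def recovery_report(
    replicates: int,
    truth: SimTruth,
    spec: ModelSpec,
    config: McmcConfig,
) -> pd.DataFrame:
    """Per-parameter bias, RMSE and 95%-credible-interval coverage across
    simulated replicates.

    Each replicate gets an independent child stream spawned from
    ``truth.seed`` (and an MCMC seed derived the same way), simulates a
    network, fits the model, and records the posterior median and central
    95% interval of every basic parameter (and tau for random-effects
    models).  Returns one row per parameter with columns truth, bias,
    mc_se (Monte-Carlo standard error of the bias), rmse, coverage.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    children = np.random.SeedSequence(truth.seed).spawn(replicates)
    ref = truth.ref()
    params = [t for t in truth.treatments if t != ref]
    track_tau = spec.effect_model == "random"
    est: dict[str, list[float]] = {p: [] for p in params}
    cover: dict[str, list[bool]] = {p: [] for p in params}
    if track_tau:
        est["tau"], cover["tau"] = [], []

    for child in children:
        s1, s2 = child.generate_state(2) % (2**31)
        rep_truth = SimTruth(
            treatments=truth.treatments,
            d_true=truth.d_true,
            tau_true=truth.tau_true,
            trials=truth.trials,
            seed=int(s1),
            reference=truth.reference,
            mu_mean=truth.mu_mean,
            mu_sd=truth.mu_sd,
            outcome=truth.outcome,
        )
        if spec.likelihood == "arm_binomial":
            net, _ = simulate_ae_network(rep_truth)
        else:
            net, _ = simulate_contrast_network(rep_truth)
        cfg = McmcConfig(
            n_chains=config.n_chains,
            burn_in=config.burn_in,
            keep=config.keep,
            thin=config.thin,
            seed=int(s2),
            adapt=config.adapt,
        )
        draws, _ = sample_posterior(net, spec, cfg)
        for p in params:
            x = draws.draws_of(f"d[{p}]")
            lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
            est[p].append(float(med))
            cover[p].append(lo <= truth.d_true[p] - truth.d_true[ref] <= hi)
        if track_tau:
            x = draws.draws_of("tau")
            lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
            est["tau"].append(float(med))
            cover["tau"].append(lo <= truth.tau_true <= hi)

    rows = []
    for p in est:
        true_val = (
            truth.tau_true
            if p == "tau"
            else truth.d_true[p] - truth.d_true[ref]
        )
        e = np.array(est[p])
        err = e - true_val
        rows.append(
            {
                "parameter": p if p == "tau" else f"d[{p}]",
                "truth": true_val,
                "bias": float(err.mean()),
                "mc_se": float(err.std(ddof=1) / np.sqrt(len(err)))
                if len(err) > 1
                else float("nan"),
                "rmse": float(np.sqrt((err**2).mean())),
                "coverage": float(np.mean(cover[p])),
                "n_replicates": replicates,
            }
        )
    return pd.DataFrame(rows)
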