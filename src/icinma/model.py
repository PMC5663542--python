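"""Bayesian mixed-treatment-comparison engine.

The consistency model expresses every comparison through *basic parameters*
d_t, the log relative effect of each treatment t versus a common reference,
so an observed contrast baseline b -> comparator k estimates d_k - d_b.

Two likelihood families are supported:

* ``contrast_normal`` — trial-level log effects y_i ~ Normal(theta_i, se_i^2)
  (log hazard ratios for survival outcomes);
* ``arm_binomial``   — per-arm event counts r_ik ~ Binomial(n_ik, p_ik) with
  logit(p_ik) = mu_i + delta_ik (adverse-event odds), mu_i the trial baseline.

Under the fixed-effect model theta_i is the consistency value d_k - d_b;
under the random-effects model trial-specific effects delta are exchangeable
around it with between-trial standard deviation tau and the usual 0.5 tau^2
within-trial covariance for multi-arm trials.

Estimation is adaptive random-walk Metropolis within Gibbs: scalar proposals
per parameter, step sizes tuned toward 44% acceptance during burn-in and then
frozen to preserve detailed balance.  The sampler is deterministic given the
seed; chains are vectorized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .data import EvidenceNetwork, NetworkError
from .diagnostics import gelman_rubin

__all__ = [
    "ModelSpec",
    "McmcConfig",
    "Design",
    "PosteriorDraws",
    "FitDiagnostics",
    "LeagueTable",
    "build_design",
    "log_posterior",
    "sample_posterior",
    "compute_dic",
    "league_table",
]

log = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    effect_model: str = "fixed"  # fixed | random
    likelihood: str = "contrast_normal"  # contrast_normal | arm_binomial
    outcome: str = "PFS"
    reference: str = "CHE"
    prior_sd_d: float = 15.0
    prior_tau_upper: float = 2.0

    def __post_init__(self):
        if self.effect_model not in ("fixed", "random"):
            raise ValueError(f"unknown effect model {self.effect_model!r}")
        if self.likelihood not in ("contrast_normal", "arm_binomial"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.prior_sd_d <= 0 or self.prior_tau_upper <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class McmcConfig:
    """MCMC schedule.  ``keep`` is retained draws per chain after thinning;
    the raw post-burn-in length per chain is keep * thin."""

    n_chains: int = 3
    burn_in: int = 10_000
    keep: int = 10_000
    thin: int = 50
    seed: int = 0
    adapt: int | None = None  # adaptation window; defaults to burn_in

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if self.keep < 500:
            raise ValueError("need >= 500 retained draws per chain")
        if min(self.burn_in, self.thin) < 1:
            raise ValueError("burn_in and thin must be positive")


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass
class Design:
    """Parameter index and data arrays for one outcome/likelihood."""

    spec: ModelSpec
    nodes: list[str]  # treatments in the outcome network, reference first
    basic: list[str]  # non-reference nodes, one d each
    param_names: list[str]
    slices: dict[str, slice]
    consistency_map: dict[tuple[str, str, str], str]
    reportable: list[str] = field(default_factory=list)
    # contrast_normal data
    y: np.ndarray | None = None
    se: np.ndarray | None = None
    X: np.ndarray | None = None  # (n_obs, n_basic): +1 comparator, -1 baseline
    obs_trial: np.ndarray | None = None
    # arm_binomial data
    r: np.ndarray | None = None
    n: np.ndarray | None = None
    Xa: np.ndarray | None = None  # per-arm contrast rows (0 for baseline arms)
    arm_trial: np.ndarray | None = None
    nonbase: np.ndarray | None = None  # indices of non-baseline arms
    trial_ids: list[str] = field(default_factory=list)
    # multi-arm grouping of the random effects (rows: trials, cols: re units)
    M: np.ndarray | None = None
    group_k: np.ndarray | None = None  # contrasts per trial

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def d_index(self, treatment: str) -> int | None:
        """Column of d_{ref,treatment} in the parameter vector (None = ref)."""
        if treatment == self.spec.reference:
            return None
        return self.basic.index(treatment)


def build_design(network: EvidenceNetwork, spec: ModelSpec) -> Design:
    """Index basic parameters and map every observation onto them."""
    outcome = spec.outcome
    if spec.likelihood == "contrast_normal":
        contrasts = network.contrasts_for(outcome)
        if not contrasts:
            raise NetworkError(f"no {outcome} contrasts to fit")
        network.require_connected(outcome)
        nodes = network.nodes_for(outcome)
    else:
        arms = [a for a in network.arms if a.ae_high is not None]
        if not arms:
            raise NetworkError("no arms carry adverse-event counts")
        # connectivity over the arm-comparison graph
        import networkx as nx

        g = nx.Graph()
        roster: dict[str, list] = {}
        for a in arms:
            roster.setdefault(a.trial_id, []).append(a)
        for trial_arms in roster.values():
            t0 = trial_arms[0].treatment_id
            for a in trial_arms[1:]:
                g.add_edge(t0, a.treatment_id)
        if g.number_of_nodes() == 0 or not nx.is_connected(g):
            comps = sorted(nx.connected_components(g), key=len, reverse=True)
            raise NetworkError(
                "adverse-event comparison graph is disconnected; components: "
                + "; ".join(str(sorted(c)) for c in comps)
            )
        nodes = [t for t in network.treatments if t in g.nodes]

    ref = spec.reference
    if ref not in nodes:
        raise NetworkError(
            f"reference treatment {ref!r} absent from the {outcome} network"
        )
    nodes = [ref] + [t for t in nodes if t != ref]
    basic = nodes[1:]
    col = {t: j for j, t in enumerate(basic)}

    names = [f"d[{t}]" for t in basic]
    slices = {"d": slice(0, len(basic))}
    cmap: dict[tuple[str, str, str], str] = {}

    design = Design(
        spec=spec, nodes=nodes, basic=basic, param_names=names, slices=slices,
        consistency_map=cmap,
        reportable=[
            t for t in nodes if network.treatments[t].reportable
        ],
    )

    def contrast_row(b: str, k: str) -> np.ndarray:
        row = np.zeros(len(basic))
        if k != ref:
            row[col[k]] = 1.0
        if b != ref:
            row[col[b]] = -1.0
        return row

    if spec.likelihood == "contrast_normal":
        trial_ids = sorted({c.trial_id for c in contrasts})
        tix = {t: i for i, t in enumerate(trial_ids)}
        design.trial_ids = trial_ids
        design.y = np.array([c.y for c in contrasts])
        design.se = np.array([c.se for c in contrasts])
        design.X = np.vstack([contrast_row(c.baseline, c.comparator) for c in contrasts])
        design.obs_trial = np.array([tix[c.trial_id] for c in contrasts])
        for c in contrasts:
            cmap[(c.trial_id, c.baseline, c.comparator)] = (
                f"d[{c.comparator}] - d[{c.baseline}]"
            )
        n_re = len(contrasts)
        re_trial = design.obs_trial
    else:
        arm_rows = []
        trial_ids = list(roster)
        tix = {t: i for i, t in enumerate(trial_ids)}
        design.trial_ids = trial_ids
        r_, n_, xa, a_trial, nonbase = [], [], [], [], []
        for trial, trial_arms in roster.items():
            base = trial_arms[0].treatment_id
            for j, a in enumerate(trial_arms):
                r_.append(a.ae_high)
                n_.append(a.n_enrolled)
                a_trial.append(tix[trial])
                if j == 0:
                    xa.append(np.zeros(len(basic)))
                else:
                    xa.append(contrast_row(base, a.treatment_id))
                    nonbase.append(len(r_) - 1)
                    cmap[(trial, base, a.treatment_id)] = (
                        f"d[{a.treatment_id}] - d[{base}]"
                    )
        design.r = np.array(r_, dtype=float)
        design.n = np.array(n_, dtype=float)
        design.Xa = np.vstack(xa)
        design.arm_trial = np.array(a_trial)
        design.nonbase = np.array(nonbase, dtype=int)
        names.extend(f"mu[{t}]" for t in trial_ids)
        slices["mu"] = slice(len(basic), len(basic) + len(trial_ids))
        n_re = len(design.nonbase)
        re_trial = design.arm_trial[design.nonbase]

    if spec.effect_model == "random":
        start = len(names)
        if spec.likelihood == "contrast_normal":
            names.extend(
                f"delta[{c.trial_id}:{c.comparator}]" for c in contrasts
            )
        else:
            names.extend(f"delta[{i}]" for i in range(n_re))
        slices["delta"] = slice(start, start + n_re)
        names.append("tau")
        slices["tau"] = slice(len(names) - 1, len(names))
        # trial indicator over random-effect units for the multi-arm covariance
        n_trials = len(design.trial_ids)
        M = np.zeros((n_trials, n_re))
        M[re_trial, np.arange(n_re)] = 1.0
        design.M = M
        design.group_k = M.sum(axis=1)

    design.param_names = names
    return design


# ---------------------------------------------------------------------------
# log posterior
# ---------------------------------------------------------------------------


class _Model:
    """Vectorized log-posterior over a (chains, params) state matrix."""

    def __init__(self, design: Design):
        self.design = design
        self.spec = design.spec
        d = design
        if d.spec.likelihood == "arm_binomial":
            self._binom_const = float(
                np.sum(gammaln(d.n + 1) - gammaln(d.r + 1) - gammaln(d.n - d.r + 1))
            )
            self._Xa_T = np.ascontiguousarray(d.Xa.T)
            if d.nonbase is not None and d.nonbase.size:
                self._Xnb_T = np.ascontiguousarray(d.Xa[d.nonbase].T)
        else:
            self._X_T = np.ascontiguousarray(d.X.T)
            self._inv_se = 1.0 / d.se
            self._norm_const = float(
                np.sum(np.log(d.se)) + 0.5 * d.y.size * _LOG2PI
            )
        if d.M is not None:
            self._M_T = np.ascontiguousarray(d.M.T)
            self._inv_k1 = 1.0 / (d.group_k + 1.0)
            self._logdet_k = float(np.sum(np.log(d.group_k + 1.0)))

    # data log-likelihood ---------------------------------------------------

    def loglik(self, theta: np.ndarray) -> np.ndarray:
        d = self.design
        sl = d.slices
        dd = theta[:, sl["d"]]
        if self.spec.likelihood == "contrast_normal":
            if self.spec.effect_model == "fixed":
                mean = dd @ self._X_T
            else:
                mean = theta[:, sl["delta"]]
            z = (d.y - mean) * self._inv_se
            return -0.5 * (z * z).sum(axis=1) - self._norm_const
        mu = theta[:, sl["mu"]]
        eta = mu[:, d.arm_trial]
        if self.spec.effect_model == "fixed":
            eta = eta + dd @ self._Xa_T
        else:
            delta = theta[:, sl["delta"]]
            eta = eta.copy()
            eta[:, d.nonbase] += delta
        return (
            (d.r * eta - d.n * np.logaddexp(0.0, eta)).sum(axis=1)
            + self._binom_const
        )

    # random-effects density ------------------------------------------------

    def _log_re(self, theta: np.ndarray) -> np.ndarray:
        """log p(delta | d, tau): per trial MVN, Var tau^2, Cov 0.5 tau^2."""
        d = self.design
        sl = d.slices
        dd = theta[:, sl["d"]]
        delta = theta[:, sl["delta"]]
        tau = theta[:, sl["tau"]][:, 0]
        if d.spec.likelihood == "contrast_normal":
            m = dd @ self._X_T
        else:
            m = dd @ self._Xnb_T
        r = delta - m
        s = r @ self._M_T  # (C, n_trials) per-trial residual sums
        tau2 = np.maximum(tau * tau, 1e-300)  # guarded; masked by the prior
        n_re = r.shape[1]
        quad = (2.0 / tau2) * (
            (r * r).sum(axis=1) - ((s * s) * self._inv_k1).sum(axis=1)
        )
        logdet = n_re * np.log(tau2 / 2.0) + self._logdet_k
        return -0.5 * (quad + logdet + n_re * _LOG2PI)

    # full posterior --------------------------------------------------------

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        d = self.design
        sl = d.slices
        sd = self.spec.prior_sd_d
        lp = -0.5 * (theta[:, sl["d"]] ** 2).sum(axis=1) / sd**2
        if "mu" in sl:
            lp = lp - 0.5 * (theta[:, sl["mu"]] ** 2).sum(axis=1) / sd**2
        if self.spec.effect_model == "random":
            tau = theta[:, sl["tau"]][:, 0]
            inside = (tau > 0) & (tau < self.spec.prior_tau_upper)
            val = lp + self.loglik(theta) + self._log_re(theta)
            return np.where(inside, val, -np.inf)
        return lp + self.loglik(theta)

    def initial_steps(self) -> np.ndarray:
        """Rough posterior-scale starting step sizes; refined by adaptation."""
        d = self.design
        if self.spec.likelihood == "contrast_normal":
            scale = float(np.median(d.se))
        else:
            scale = float(2.0 / np.sqrt(np.median(d.n)))
        step = np.full(d.n_params, max(min(scale * 2.0, 1.0), 1e-8))
        if "tau" in d.slices:
            step[d.slices["tau"]] = 0.1 * self.spec.prior_tau_upper
        return step

    def initial_state(self, rng: np.random.Generator, n_chains: int) -> np.ndarray:
        """Overdispersed data-informed starting points (mode + scaled jitter)."""
        d = self.design
        sl = d.slices
        theta = np.zeros((n_chains, d.n_params))
        if self.spec.likelihood == "contrast_normal":
            # generalized-least-squares centre of the fixed-effect model
            w = 1.0 / d.se**2
            A = d.X.T * w @ d.X + np.eye(len(d.basic)) / self.spec.prior_sd_d**2
            d_hat = np.linalg.solve(A, d.X.T @ (w * d.y))
            scale = float(np.median(d.se))
            theta[:, sl["d"]] = d_hat + 2.0 * scale * rng.standard_normal(
                (n_chains, len(d.basic))
            )
            if "delta" in sl:
                m = theta[:, sl["d"]] @ d.X.T
                theta[:, sl["delta"]] = m + 2.0 * scale * rng.standard_normal(
                    m.shape
                )
        else:
            rate = (d.r + 0.5) / (d.n + 1.0)
            logit = np.log(rate / (1.0 - rate))
            for i in range(len(d.trial_ids)):
                theta[:, sl["mu"].start + i] = logit[d.arm_trial == i].mean()
            theta[:, sl["d"]] += 0.5 * rng.standard_normal((n_chains, len(d.basic)))
            theta[:, sl["mu"]] += 0.5 * rng.standard_normal(
                (n_chains, len(d.trial_ids))
            )
            if "delta" in sl:
                theta[:, sl["delta"]] = 0.5 * rng.standard_normal(
                    (n_chains, sl["delta"].stop - sl["delta"].start)
                )
        if self.spec.effect_model == "random":
            theta[:, sl["tau"]] = rng.uniform(
                0.05 * self.spec.prior_tau_upper,
                0.5 * self.spec.prior_tau_upper,
                (n_chains, 1),
            )
        return theta


def log_posterior(state: np.ndarray, network: EvidenceNetwork, spec: ModelSpec) -> float:
    """Scalar log posterior density of one parameter vector."""
    design = build_design(network, spec)
    state = np.asarray(state, dtype=float)
    if state.shape != (design.n_params,):
        raise ValueError(
            f"state has shape {state.shape}, design expects ({design.n_params},)"
        )
    return float(_Model(design).log_posterior(state[None, :])[0])


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Retained draws, shaped (keep, n_chains, n_params), with labels."""

    samples: np.ndarray
    param_names: list[str]
    design: Design
    config: McmcConfig
    acceptance: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.samples.shape[0] * self.samples.shape[1]

    def flat(self) -> np.ndarray:
        """All chains concatenated: (keep * n_chains, n_params)."""
        return self.samples.reshape(-1, self.samples.shape[2])

    def by_chain(self) -> np.ndarray:
        """(n_chains, keep, n_params) view for convergence diagnostics."""
        return np.swapaxes(self.samples, 0, 1)

    def basic_draws(self, include_reference: bool = True) -> tuple[list[str], np.ndarray]:
        """Draws of the basic parameters; the reference contributes zeros."""
        flat = self.flat()
        sl = self.design.slices["d"]
        mat = flat[:, sl]
        names = list(self.design.basic)
        if include_reference:
            names = [self.design.spec.reference] + names
            mat = np.hstack([np.zeros((mat.shape[0], 1)), mat])
        return names, mat

    def draws_of(self, name: str) -> np.ndarray:
        j = self.param_names.index(name)
        return self.flat()[:, j]


@dataclass
class FitDiagnostics:
    dbar: float = float("nan")
    pd: float = float("nan")
    dic: float = float("nan")
    psrf: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def max_psrf(self) -> float:
        return max(self.psrf.values()) if self.psrf else float("nan")


@dataclass
class LeagueTable:
    """All-pairs pooled ratios: entry (column vs row) = exp(d_col - d_row).

    Ratios below 1 favour the column treatment for hazard/odds outcomes.
    """

    treatments: list[str]
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    orientation: str = "column_vs_row"

    def entry(self, column: str, row: str) -> tuple[float, float, float]:
        i = self.treatments.index(column)
        j = self.treatments.index(row)
        return (
            float(self.median[j, i]),
            float(self.lower[j, i]),
            float(self.upper[j, i]),
        )

    def significant(self, column: str, row: str) -> bool:
        _, lo, hi = self.entry(column, row)
        return not (lo <= 1.0 <= hi)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


def _run_sampler(
    model: _Model, config: McmcConfig
) -> tuple[np.ndarray, np.ndarray]:
    from . import _kernel

    design = model.design
    spec = design.spec
    rng = np.random.default_rng(config.seed)
    theta = model.initial_state(rng, config.n_chains)
    step = model.initial_steps()
    adapt_until = config.adapt if config.adapt is not None else config.burn_in

    neg1 = np.full(0, -1, dtype=np.int64)

    def cols(mat: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
        """Signed basic-parameter column indices of ±1 contrast rows."""
        if mat is None or mat.size == 0:
            return neg1, neg1
        plus = np.full(mat.shape[0], -1, dtype=np.int64)
        minus = np.full(mat.shape[0], -1, dtype=np.int64)
        for i, row in enumerate(mat):
            for j, v in enumerate(row):
                if v > 0:
                    plus[i] = j
                elif v < 0:
                    minus[i] = j
        return plus, minus

    if spec.likelihood == "contrast_normal":
        like_code = _kernel.LIKE_CONTRAST
        y, inv_se = design.y, 1.0 / design.se
        obs_plus, obs_minus = cols(design.X)
        r = n = np.zeros(0)
        arm_trial = arm_plus = arm_minus = arm_re = neg1
        re_plus, re_minus = obs_plus, obs_minus
        n_mu = 0
    else:
        like_code = _kernel.LIKE_BINOMIAL
        y, inv_se = np.zeros(0), np.zeros(0)
        obs_plus = obs_minus = neg1
        r, n = design.r, design.n
        arm_trial = design.arm_trial.astype(np.int64)
        arm_plus, arm_minus = cols(design.Xa)
        arm_re = np.full(len(r), -1, dtype=np.int64)
        if design.nonbase is not None:
            arm_re[design.nonbase] = np.arange(len(design.nonbase))
        re_plus, re_minus = cols(
            design.Xa[design.nonbase] if design.nonbase is not None else None
        )
        n_mu = len(design.trial_ids)

    if spec.effect_model == "random":
        random_effects = 1
        re_trial = (
            design.obs_trial if spec.likelihood == "contrast_normal"
            else design.arm_trial[design.nonbase]
        ).astype(np.int64)
        group_k = design.group_k
        delta_off = design.slices["delta"].start
        tau_idx = design.slices["tau"].start
    else:
        random_effects = 0
        re_trial = neg1
        group_k = np.zeros(0)
        delta_off = tau_idx = 0
        re_plus = re_minus = neg1

    kernel_seed = int(rng.integers(0, 2**31 - 1))
    draws, rates = _kernel.run_mcmc(
        theta,
        config.burn_in, config.keep, config.thin, adapt_until, kernel_seed,
        like_code, random_effects,
        np.asarray(y, float), np.asarray(inv_se, float), obs_plus, obs_minus,
        np.asarray(r, float), np.asarray(n, float),
        arm_trial, arm_plus, arm_minus, arm_re,
        re_plus, re_minus, re_trial, np.asarray(group_k, float),
        len(design.basic), n_mu,
        design.slices["d"].stop if n_mu else 0, delta_off, tau_idx,
        1.0 / spec.prior_sd_d**2, spec.prior_tau_upper,
        step, 0.44,
    )
    return draws, rates


def sample_posterior(
    network: EvidenceNetwork, spec: ModelSpec, config: McmcConfig
) -> tuple[PosteriorDraws, FitDiagnostics]:
    """Fit the model by MCMC; deterministic given ``config.seed``.

    Reported-parameter convergence is assessed by the potential scale
    reduction factor; any PSRF above 1.05 flags the fit non-converged (the
    draws are still returned, with a warning).
    """
    design = build_design(network, spec)
    model = _Model(design)
    samples, rates = _run_sampler(model, config)
    draws = PosteriorDraws(
        samples=samples,
        param_names=list(design.param_names),
        design=design,
        config=config,
        acceptance=rates,
    )
    diag = compute_dic(draws, network, spec)
    # PSRF over reported parameters: basic d's (and tau for random models)
    chains = draws.by_chain()
    report_idx = list(range(len(design.basic)))
    if "tau" in design.slices:
        report_idx.append(design.slices["tau"].start)
    psrf = gelman_rubin(chains[:, :, report_idx])
    diag.psrf = {
        design.param_names[j]: float(psrf[k]) for k, j in enumerate(report_idx)
    }
    diag.acceptance = {
        design.param_names[j]: float(rates[j]) for j in range(design.n_params)
    }
    diag.converged = all(v <= 1.05 for v in diag.psrf.values())
    if not diag.converged:
        log.warning(
            "fit flagged non-converged: max PSRF %.3f", diag.max_psrf
        )
    return draws, diag


def compute_dic(
    draws: PosteriorDraws, network: EvidenceNetwork, spec: ModelSpec
) -> FitDiagnostics:
    """Deviance information criterion from the retained draws.

    Dbar is the posterior mean of -2 log-likelihood, pD = Dbar - D(theta_bar)
    the effective number of parameters, DIC = Dbar + pD.
    """
    model = _Model(draws.design)
    flat = draws.flat()
    dev = -2.0 * model.loglik(flat)
    dbar = float(dev.mean())
    dhat = float(-2.0 * model.loglik(flat.mean(axis=0, keepdims=True))[0])
    pd_ = dbar - dhat
    return FitDiagnostics(dbar=dbar, pd=pd_, dic=dbar + pd_)


def league_table(
    draws: PosteriorDraws, include: list[str] | None = None
) -> LeagueTable:
    """All-pairs posterior ratio table from the basic-parameter draws.

    Entry (column c, row r) is exp of the posterior median / 2.5 / 97.5
    percentiles of d_c - d_r.  Medians satisfy entry(a,b) = 1/entry(b,a)
    exactly since each cell is a monotone transform of the same draw-wise
    differences.  Non-reportable auxiliary nodes are excluded by default.
    """
    names, mat = draws.basic_draws(include_reference=True)
    if include is None:
        include = [t for t in names if t in draws.design.reportable]
    cols = [names.index(t) for t in include]
    T = len(include)
    med = np.ones((T, T))
    lo = np.ones((T, T))
    hi = np.ones((T, T))
    for a in range(T):
        for b in range(T):
            if a == b:
                continue
            diff = mat[:, cols[b]] - mat[:, cols[a]]  # column b vs row a
            q = np.percentile(diff, [2.5, 50.0, 97.5])
            lo[a, b] = np.exp(q[0])
            med[a, b] = np.exp(q[1])
            hi[a, b] = np.exp(q[2])
    return LeagueTable(treatments=include, median=med, lower=lo, upper=hi)
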