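"""Compiled inner loop of the Metropolis-within-Gibbs sampler.

The kernel mirrors the reference log-posterior in :mod:`icinma.model` up to
additive constants (which cancel in acceptance ratios): contrast-normal or
arm-binomial likelihood, fixed or random effects with the multi-arm
tau^2 (I+J)/2 covariance evaluated through its closed-form inverse.  The
surrounding package computes DIC, diagnostics and reported densities with
the uncompiled reference implementation, which doubles as the correctness
oracle for this kernel in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LIKE_CONTRAST = 0
LIKE_BINOMIAL = 1


@njit(cache=False)
def run_mcmc(
    theta,          # (C, P) initial states, modified in place
    burn_in, keep, thin, adapt_until, seed,
    like_code, random_effects,
    y, inv_se, obs_plus, obs_minus,          # contrast data (n_obs)
    r, n, arm_trial, arm_plus, arm_minus, arm_re,  # binomial data (n_arms)
    re_plus, re_minus, re_trial, group_k,    # RE units: contrast cols, trial map
    n_basic, n_mu, mu_off, delta_off, tau_idx,
    prior_inv_var, tau_upper,
    step,            # (P,) initial proposal scales, modified in place
    target,
):
    np.random.seed(seed)
    C, P = theta.shape
    n_obs = y.shape[0]
    n_arms = r.shape[0]
    n_re = re_trial.shape[0]
    n_trials = group_k.shape[0]

    def logpost(th):
        lp = 0.0
        for b in range(n_basic):
            lp -= 0.5 * th[b] * th[b] * prior_inv_var
        if like_code == LIKE_BINOMIAL:
            for i in range(mu_off, mu_off + n_mu):
                lp -= 0.5 * th[i] * th[i] * prior_inv_var
        tau = 0.0
        if random_effects == 1:
            tau = th[tau_idx]
            if tau <= 0.0 or tau >= tau_upper:
                return -np.inf
        # data likelihood
        if like_code == LIKE_CONTRAST:
            if random_effects == 0:
                for i in range(n_obs):
                    m = 0.0
                    if obs_plus[i] >= 0:
                        m += th[obs_plus[i]]
                    if obs_minus[i] >= 0:
                        m -= th[obs_minus[i]]
                    z = (y[i] - m) * inv_se[i]
                    lp -= 0.5 * z * z
            else:
                for i in range(n_obs):
                    z = (y[i] - th[delta_off + i]) * inv_se[i]
                    lp -= 0.5 * z * z
        else:
            for a in range(n_arms):
                eta = th[mu_off + arm_trial[a]]
                if random_effects == 1:
                    if arm_re[a] >= 0:
                        eta += th[delta_off + arm_re[a]]
                else:
                    if arm_plus[a] >= 0:
                        eta += th[arm_plus[a]]
                    if arm_minus[a] >= 0:
                        eta -= th[arm_minus[a]]
                if eta > 0.0:
                    lse = eta + np.log1p(np.exp(-eta))
                else:
                    lse = np.log1p(np.exp(eta))
                lp += r[a] * eta - n[a] * lse
        # random-effects density: per trial MVN, Var tau^2, Cov tau^2/2
        if random_effects == 1:
            tau2 = tau * tau
            ssq = 0.0
            s_trial = np.zeros(n_trials)
            for u in range(n_re):
                m = 0.0
                if re_plus[u] >= 0:
                    m += th[re_plus[u]]
                if re_minus[u] >= 0:
                    m -= th[re_minus[u]]
                res = th[delta_off + u] - m
                ssq += res * res
                s_trial[re_trial[u]] += res
            quad = 0.0
            for t in range(n_trials):
                quad += s_trial[t] * s_trial[t] / (group_k[t] + 1.0)
            quad = (2.0 / tau2) * (ssq - quad)
            lp -= 0.5 * (quad + n_re * np.log(tau2 / 2.0))
        return lp

    lp = np.empty(C)
    for c in range(C):
        lp[c] = logpost(theta[c])

    total = burn_in + keep * thin
    draws = np.empty((keep, C, P))
    acc = np.zeros(P)
    acc_n = 0
    kept = 0
    for it in range(total):
        adapting = it < adapt_until
        for j in range(P):
            n_acc = 0
            for c in range(C):
                old = theta[c, j]
                theta[c, j] = old + step[j] * np.random.randn()
                lp_new = logpost(theta[c])
                if np.log(np.random.rand()) < lp_new - lp[c]:
                    lp[c] = lp_new
                    n_acc += 1
                else:
                    theta[c, j] = old
            rate = n_acc / C
            if adapting:
                step[j] *= np.exp((rate - target) / (1.0 + it) ** 0.6 * 3.0)
            elif it >= burn_in:
                acc[j] += rate
        if not adapting and it >= burn_in:
            acc_n += 1
            if (it - burn_in + 1) % thin == 0:
                draws[kept] = theta
                kept += 1
    if acc_n > 0:
        for j in range(P):
            acc[j] /= acc_n
    return draws[:kept], acc
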