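# Methods

## The model

The package estimates the relative efficacy and safety of ten treatment
strategies for advanced melanoma (chemotherapy, ipilimumab, tremelimumab,
nivolumab, pembrolizumab, and five ipilimumab combinations) from randomized
trials that compare only subsets of them, by joint synthesis of direct and
indirect evidence over the comparison network (mixed treatment comparison).

All comparisons are expressed through *basic parameters* `d_t`, the log
relative effect of treatment `t` versus a common reference (chemotherapy,
`CHE`, the best-connected node).  Under the consistency assumption every
contrast between treatments `b` and `k` equals `d_k − d_b`, so a connected
network identifies all pairwise effects.  The consistency identity holds
draw-wise by construction; whether it is compatible with the data is checked
separately (see below).

Two likelihoods cover the two outcome families:

* **Contrast-level normal** (survival outcomes).  Each trial reports a hazard
  ratio with a 95% CI per non-reference arm.  The observed log HR
  `y_i ~ Normal(θ_i, se_i²)`, with `se_i = (ln U_i − ln L_i) / (2 z₀.₉₇₅)`
  recovered from the CI bounds using the exact normal quantile
  (1.959964...), not a rounded 1.96.
* **Arm-level binomial** (adverse events).  Event counts
  `r_ik ~ Binomial(n_ik, p_ik)` with `logit(p_ik) = μ_i + δ_ik`, where
  `μ_i` is the trial's baseline log-odds and `δ` is zero on the baseline arm.

Under the **fixed-effect** model `θ_i` (or `δ_ik`) is pinned to the
consistency value `d_k − d_b`.  Under the **random-effects** model
trial-specific effects are exchangeable around it with between-trial standard
deviation `τ`; within a multi-arm trial the joint distribution has
`Var = τ²` and `Cov = τ²/2`, evaluated through the closed-form inverse of
the `τ²(I+J)/2` covariance (quadratic form `(2/τ²)[Σr² − (Σr)²/(K+1)]`,
determinant `(τ²/2)^K (K+1)` for `K` contrasts).

**Priors.**  The source analysis does not state its priors; we use
conventional vague choices: `d, μ ~ Normal(0, 15²)` on the log scale,
`τ ~ Uniform(0, 2)` for log hazard ratios and `Uniform(0, 5)` for log odds.
Priors enter the posterior as unnormalized kernels.  A dominance check in
the test suite verifies that widening the `d` prior tenfold moves league
medians by less than 0.01 on the log scale, so these choices are immaterial.

## Estimation

Sampling is adaptive random-walk Metropolis within Gibbs: scalar Gaussian
proposals per parameter, with step sizes tuned toward 44% acceptance by a
Robbins–Monro recursion during burn-in and frozen afterwards to preserve
detailed balance.  The inner loop is compiled (numba); the uncompiled
reference log-posterior drives DIC and reported densities and doubles as
the kernel's correctness oracle in the tests (closed-form conjugate and
inverse-variance checks).  Chains start from overdispersed data-informed points (the
generalized-least-squares centre plus jitter of twice the typical standard
error), and initial step sizes are set from the data scale so that very
precise synthetic datasets adapt correctly.  The sampler is fully
deterministic given the seed; chains are vectorized.

The primary schedule runs 3 chains with a 10,000-iteration burn-in and
10,000 retained draws per chain at a thinning interval of 50 (30,000
retained draws total).  Convergence is monitored by the potential scale
reduction factor `√(((n−1)/n·W + B/n)/W)` on the reported parameters
(`d`, and `τ` for random-effects models); any PSRF above 1.05 flags the fit
non-converged (the draws are still returned with a warning, and the CLI exit
status reflects it).  Constant identical chains are reported as PSRF 1 by
convention.

Model choice uses the deviance information criterion,
`DIC = D̄ + pD` with `pD = D̄ − D(θ̄)` computed from the data likelihood;
the reporting model is the lower-DIC fit, with ties within 3 units resolved
in favour of fixed effects.  On the melanoma PFS network the fixed-effect
model wins (DIC −6.0 vs −4.5), consistent with the low observed
heterogeneity.

## Data handling choices

* **Dose arms.**  Two trials randomize two pembrolizumab schedules against
  one control.  The default `pool` policy combines the two dose contrasts by
  inverse-variance fixed-effect pooling on the log scale (enrolments summed,
  provenance recorded), mirroring a single-node treatment definition.
  `keep_first` and `keep_all_as_distinct` are available alternatives.
* **Auxiliary node.**  One three-arm trial is anchored on gp100 alone, a
  regimen outside the reportable treatment set.  The default `aux_node`
  policy keeps gp100 as a likelihood-only, non-reportable node, preserving
  the trial's internal randomization; `rebase_independent` instead
  re-anchors the trial on ipilimumab by differencing the two published
  contrasts (`y = y₁ − y₂`, `se = √(se₁² + se₂²)`), an independence
  approximation.
* **Contrast orientation.**  Contrasts are stored baseline-anchored (the
  trial's reference arm is the baseline); re-orientation is a sign flip.
  Observed contrasts sharing a baseline within a three-arm trial are treated
  as independent in the likelihood: the observation-level correlation cannot
  be reconstructed from published per-contrast CIs.  This is a documented
  approximation; the random-effects `δ`s still carry the `τ²/2` within-trial
  covariance.
* **Missing effects.**  Trials without a usable HR contribute arms (and, in
  principle, adverse-event counts) but no survival contrast.  When a trial
  reports only a log-rank p-value with total events, or only median survival
  times, the extraction helpers reconstruct `(y, se)` by the standard
  observed-minus-expected approximation (`V = E·R/(1+R)²`) or a point HR
  from inverted medians under exponential survival; the median-based value
  carries no standard error and is excluded from likelihoods unless one is
  attached.  Odds ratios from arm counts use the Haldane–Anscombe 0.5
  continuity correction, applied only when a zero cell exists.

## League tables, ranking, pairwise checks

League-table cells report, for each ordered pair, the posterior median and
2.5/97.5 percentiles of `exp(d_col − d_row)` computed from the draw-wise
differences (ratios below 1 favour the column treatment, and a cell is
flagged significant when its interval excludes 1).  Because each cell is a
monotone transform of the same draws, `entry(a,b) = 1/entry(b,a)` holds
exactly; medians of different cells multiply only approximately (the median
is not additive), while the underlying draw-wise consistency identity is
exact.

Rank probabilities are empirical frequencies of each rank across draws,
ordering treatments by their `d` values under the outcome's direction
(lower hazard/odds better).  Exact ties — impossible for continuous
posteriors, but reachable in degenerate tests — are broken by a uniform
random permutation from a dedicated seeded generator.  Auxiliary nodes are
excluded from rankings and reported league tables.  The cumulative rank
score (mean cumulative rank probability over ranks 1..T−1) condenses a
rankogram to [0, 1].

Traditional pairwise meta-analysis pools each directly-compared pair by
inverse variance; the DerSimonian–Laird moment estimator supplies `τ²` for
random-effects pooling, with Cochran's `Q`, `I² = max(0, (Q−df)/Q)` and a
severe-heterogeneity flag at `I² > 50%` or `p_Q < 0.10`.  Consistency is
assessed per comparison as interval overlap (plus the log-difference)
between the direct pooled CI and the network credible interval — matching
the way such checks are usually displayed — rather than by a formal
node-splitting model, which is out of scope.  Funnel diagnostics center
every contrast on its own comparison's fixed-effect direct pool
(comparison-adjusted funnel), so single-study comparisons sit exactly at
zero and the inverse-variance-weighted mean within each comparison is zero
by construction.

## Synthetic data and calibration

The generator emulates exactly the structures the likelihoods assume:
contrasts drawn as `δ ~ MVN(d-contrast, τ²(I+J)/2)` per trial then
`y ~ Normal(δ, se²)`, and adverse-event counts as
`r ~ Binomial(n, expit(μ_i + δ))` with `μ_i ~ Normal(mu_mean, mu_sd²)`
(defaults −1.5 and 0.4, i.e. baseline event rates around 18%).  The default
geometry mirrors the melanoma network: a reference hub with spokes plus one
three-arm loop closing a cycle (4 nodes, 5 trials, default contrast se 0.15
and 200 patients per arm, magnitudes typical of the real table).  One root
seed spawns independent per-replicate child streams via
`numpy.random.SeedSequence`, so any replicate is independently reproducible.

What the generator does *not* emulate: patient-level event times (the model
operates on summary contrasts, so the generator does too), informative
censoring, dose–response structure, or correlated observation errors within
multi-arm trials.  Passing calibration therefore shows that the estimation
machinery is correct for the assumed data-generating process, not that the
assumptions hold in any particular real evidence base.

Calibration runs refit hundreds of simulated networks at reduced MCMC
schedules (2 chains, 500 retained draws at thinning 2 after an 800–1,200
iteration burn-in — chosen to keep per-fit Monte-Carlo error well below the
simulation spread) and check per-parameter bias against its Monte-Carlo
standard error and 95%-interval coverage against the nominal rate.

## Numerical and degenerate-input conventions

* `τ` proposals outside the uniform prior support score `−∞` and are
  rejected, not raised.
* A degenerate posterior (all draws equal) yields `pD = 0`.
* Networks that are disconnected for the requested outcome are refused with
  the components listed, both at model build and after the low-risk
  sensitivity restriction; an ingest row with an inverted CI, an unknown
  treatment code or a duplicated contrast is rejected with the offending row
  named.
* League rendering is byte-stable: fixed treatment order, two-decimal
  ratios, dash on the diagonal.

## Known limitations

* The three trials carrying masking bias are not named in the source; the
  shipped risk-flag table is a constructed stand-in (marked synthetic) that
  flags three open-label trials, which is sufficient to exercise the
  sensitivity restriction but should be replaced for substantive reuse.
* Per-arm adverse-event counts and per-trial OS hazard ratios are not
  published in usable form for this evidence base, so the OS and AE code
  paths are validated on synthetic data only.
* One published pairwise PFS value (the combination versus nivolumab, 0.88)
  is arithmetically incompatible with the same publication's other pooled
  values under any consistency model (0.38/0.50 ≈ 0.76); our fit gives 0.78.
* No node-splitting inconsistency model, no Hamiltonian sampling, no
  Egger/Begg asymmetry test, and no benefit–risk composite ranking.
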