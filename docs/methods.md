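# Methods

`blastdm` models two-choice diagnostic-image decisions — classifying a
white-blood-cell image as a *blast* (the malignant signal class) or a
*non-blast* — under three instruction regimes: accuracy emphasis (5 s
response window), speed emphasis (1 s window), and expectation bias (a
pre-stimulus cue, valid 65% of the time, indicating a likely blast). Two
complementary models are fit hierarchically: equal-variance signal
detection theory (SDT) and the diffusion decision model (DDM).

## The diffusion model

Evidence `X(t)` starts at `z` and evolves as `dX = v dt + s dW` between an
upper boundary `a` ("blast") and a lower boundary 0 ("non-blast"). The
response is the boundary reached; the response time is the first-passage
time plus a non-decision offset `t_nd` (encoding + motor). Within-trial
noise is fixed at `s = 0.1` to resolve the model's scale degeneracy. The
mean drift depends on the stimulus cell: `d_be`, `d_bh` for easy/hard
blasts (positive expected) and `d_nbe`, `d_nbh` for easy/hard non-blasts
(negative expected). Trial-to-trial variability follows the canonical
full model: drift `~ Normal(mean drift, s_d)`, start point
`~ Uniform(z ± s_z/2)`. In the bias condition, cue-present trials use an
alternative mean start point `z_cue` (sharing `s_z`), so a cue-induced
prior bias appears as `z_cue > z`.

**Simulator.** Trials are simulated by an Euler scheme with a
Brownian-bridge absorption correction: the within-step increment is exact
for constant drift, and after every interior step the exact bridge
crossing probability `exp(-2 (b - x)(b - x') / (s² dt))` is applied for
each boundary. Absorption times are recorded at mid-step, removing the
`dt/2` discretization bias. This keeps coarse steps accurate: at
`dt = 10 ms` the simulated choice probabilities and RT distributions are
indistinguishable from the analytic series solution at 10⁵ draws
(Kolmogorov–Smirnov distance < 0.01, the documented equivalence
threshold). Residual error comes only from neglected double-boundary
crossings within one step, which is negligible at these step sizes. The
generator default is `dt = 1 ms`; the likelihood uses `dt = 5–10 ms` for
speed (set in `PDAConfig`).

**Analytic oracles.** For the no-variability submodel (`s_d = s_z = 0`)
the package carries the closed-form absorption probability and the
classical small-time/large-time series solutions of the first-passage
density (switching at scaled time 0.25, truncated adaptively to 1e-8).
These never enter a fit; they exist to pin the simulator and the PDA
estimate down in tests.

## PDA likelihood

The full DDM has no tractable likelihood, so it is approximated by
probability density approximation: per design cell (stimulus × difficulty
× cue state), `n_syn` synthetic trials are simulated at the proposed
parameters, split by response, and kernel-smoothed into defective
densities (Gaussian kernel, Silverman bandwidth `0.9 min(SD, IQR/1.34)
n^(-1/5)`, floored at 1e-4 s; mixture weight = the response's choice
proportion). Observed log-likelihood is the sum of log smoothed densities,
floored at 1e-10. Simulated and observed trials that exceed the condition
deadline are both excluded, so the densities are conditioned on responding
in time; the timeout probability itself is not modeled. KDE evaluation is
accelerated by binning the synthetic sample into 256 histogram bins (bin
width far below the bandwidth); the oracle-equivalence test bounds the
combined KDE + binning error at mean absolute error < 0.05 on a 50-point
RT grid at `n_syn = 10⁵` (densities are O(1); most of that budget is
bandwidth bias at the sharp post-`t_nd` onset).

Defaults: `n_syn = 10,000` per cell for standalone density estimates;
hierarchical fits use `n_syn = 2,000` as a deliberate compute/noise
trade-off, relying on the sampler's noise tolerance (below). The PDA
estimate is noisy; its SD shrinks with `n_syn` at roughly the root-n rate
(slightly faster in practice, as bias-related components decay faster).

## Sampling

Parameters are sampled on an unconstrained scale: drifts raw, `log a`,
`log s_d`, `log s_z`, `log t_nd`, `logit(z/a)`, `logit(z_cue/a)`. The
joint constraint `z ± s_z/2 ∈ (0, a)` is enforced by likelihood rejection,
so retained draws always satisfy it. Individual vectors are modeled as
component-wise Normal(μ, σ) on this scale; group scales get half-Normal(0,
0.5) priors, group locations Normal priors (drifts N(0, 2²); `log a`
centered at log 0.15; `logit z/a` centered at 0; `log t_nd` centered at
log 0.3 — weakly informative, all configurable).

The sampler is differential-evolution MCMC: proposals `θ* = θ_k +
γ(θ_m − θ_n) + ε` with `γ = 2.38/√(2D)`, jitter `ε ~ U(-0.001, 0.001)`,
and a 10% chance of a `γ = 1` jump. A migration move (cyclic state
adoption among a random subset of 2–3 chains, Metropolis-accepted per
chain, probability 0.05 per sweep) rescues stuck or outlier chains;
subsets are kept small because aggressive state duplication erodes
ensemble diversity. Hierarchical fits alternate: per-participant DE
crossover (group density as prior), then group-level updates — exact
normal-normal Gibbs for μ, DE/random-walk Metropolis on `log σ`.

**Noisy likelihoods.** With PDA, the stored log-likelihood of the current
state is reused ("resample on accept") and all stored values are freshly
re-evaluated every 20 sweeps, bounding the lifetime of a lucky noisy
estimate. A full re-evaluation policy per sweep is available at twice the
cost.

**Starting values.** Chains start scattered around closed-form EZ-style
moment-matching estimates per participant (accuracy + RT mean/variance
inverted for drift, threshold, and non-decision time per stimulus cell).
Prior-drawn overdispersed starts are supported but, at desk-scale burn-in
budgets, can strand the whole ensemble on a broad high-`s_d`/high-`a`
ridge far below the data-supported region; data-driven starts remove that
failure mode without touching the target distribution.

**Diagnostics.** Split rank-normalized R-hat and effective sample size
per retained parameter (via arviz); `strict` fits fail on R-hat > 1.1.

## SDT model

Equal-variance SDT with blast as signal: hit rate `Φ(d'/2 − c)`,
false-alarm rate `Φ(−d'/2 − c)`; `c` is measured from the midpoint, so
negative values are liberal (blast-favoring). Individual `(d'_i, c_i)` are
Normal(μ, σ) per experience group (novice / inexperienced / experienced
pathologists), binomial likelihood, same DE-MCMC machinery. Fits are run
separately per instruction condition and, in the bias condition, per cue
state. The closed-form estimator `d' = Φ⁻¹(h) − Φ⁻¹(f)` (with a
0.5/(n+1)-style continuity correction at boundary rates) serves as the
oracle the Bayesian fit must approach for a single participant under flat
priors at large n.

## Bayes factors

JZS t-test Bayes factors integrate the noncentral-t likelihood over a
Cauchy effect-size prior (scale 0.707 by default) by adaptive quadrature
(tolerance 1e-8); correlation Bayes factors integrate the exact sampling
density of r over a stretched-beta prior on ρ (width 1 → uniform).
"Posterior p values" on fitted group-level parameters are read as
two-sided tail probabilities `2 min(P(A−B>0), P(A−B<0))` of the difference
of posterior draws — the most common reading of posterior-based t-test
reports; this interpretation is a package choice and is surfaced here
deliberately.

## Synthetic experiment generator

The generator reproduces the task design exactly: 6 blocks × 100 trials,
each block 25 trials of each stimulus cell, fully randomized; one
accuracy, one speed, one bias block in random order, the order then
repeated; 5 s / 1 s deadlines; in bias blocks a cue on exactly half the
trials. Cue validity and exact cell balance are reconciled by stratified
assignment: cued trials are 65% blast up to rounding, the first bias block
rounding toward the cue (33/50) and the second down (32/50), so the
two-block total is exactly 65%. Cue-absent bias trials keep the 50/50
stimulus base rate (the design leaves this open; 50/50 is the neutral
reading). RTs run from image onset; fixation (250 ms) and cue display
(500 ms) are metadata. Training/practice phases are not emulated — models
are fit to main-task data. Timeouts are retained in the trial table
(`choice = timeout`) and excluded from all likelihoods, with counts
logged; whether the original task recorded post-deadline responses is
unknown, and exclusion is the conservative default.

Ground-truth parameter distributions for recovery studies are
package-chosen defaults: novice
drifts (0.18, 0.10, −0.22, −0.07) for (easy-blast, hard-blast,
easy-non-blast, hard-non-blast) — hard non-blasts hardest, easy non-blasts
easiest — thresholds 0.14/0.08/0.13 for accuracy/speed/bias (speed
pressure = lower threshold), `z/a = 0.5`, `z_cue/a = 0.65`, `t_nd ≈
0.3–0.35 s`, with ~10–25% relative group scales; pathologists get larger
drift magnitudes. These produce 70–90% accuracies and sub-second decision
times, matching the qualitative behavioral regime. SDT ground truths use
group discriminabilities ordered novice < inexperienced < experienced
(1.45 / 2.22 / 2.73 in the accuracy condition) with mildly liberal
criteria. What passing recovery tests show is that the pipeline estimates
its own data-generating process correctly at realistic sizes; real data
add model misspecification (contaminant RTs, slow drifts of attention,
image-level idiosyncrasies) that the generator deliberately does not
emulate.

Generation truncates group distributions to each parameter's natural
support and redraws the rare participant whose start-point geometry
violates `z ± s_z/2 ⊂ (0, a)`.

## Problem sizes and numerical choices

Desk-scale defaults used by the validation suite and the acceptance
script, chosen as the smallest sizes at which the checks are stable:
recovery cohort 20 participants × 600 trials fit per condition with 12
chains, 150 burn-in + 100 retained sweeps, `n_syn = 2,000`, `dt = 10 ms`;
qualitative-effect replicate fits use 6-participant cohorts. Oracle
comparisons use 10⁵ draws. Quadrature tolerances 1e-8; density floor
1e-10; series truncation 1e-8.

## Known limitations

- PDA makes the posterior approximate; the bias shrinks with `n_syn` but
  is nonzero, and group-scale parameters (σ) are the least well
  identified.
- `s_d` is weakly identified at a few hundred trials per participant —
  a known property of the full DDM, not of this implementation.
- No across-trial `t_nd` variability, collapsing bounds, or urgency
  signals; the timeout process is censored, not modeled.
- The regression/model-averaging analysis relating visual-ability scores
  to DDM parameters is out of scope; `nomt_accuracy` is carried as an
  optional covariate column only.
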