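# blastdm

Hierarchical Bayesian modeling of two-choice diagnostic-image decisions:
how novices and pathologists decide whether a white-blood-cell image shows
a *blast* (the malignant cell class in acute leukemia) under time
pressure, accuracy emphasis, or a probabilistic expectation cue.

The package is aimed at decision-science and medical-image-perception
researchers who want to go beyond accuracy scores: it decomposes behavior
into interpretable cognitive parameters and validates every stage by
parameter recovery on synthetic cohorts that reproduce the task design
(6 blocks × 100 trials; equal numbers of easy/hard × blast/non-blast
images; 5 s accuracy and 1 s speed deadlines; a 65%-valid pre-stimulus cue
on half the bias-block trials).

## Models

**Equal-variance signal detection theory.** Hit and false-alarm rates
h = Φ(d′/2 − c), f = Φ(−d′/2 − c), with discriminability d′ and criterion
c (negative = liberal toward "blast"). Individual (d′ᵢ, cᵢ) are
Normal(μ, σ) per experience group; binomial likelihood.

**Diffusion decision model.** Evidence X(t) diffuses from start point z
between boundaries 0 ("non-blast") and a ("blast"), dX = v·dt + s·dW with
s = 0.1 fixed. Stimulus-cell drifts d_BE, d_BH (blasts, positive) and
d_NBE, d_NBH (non-blasts, negative); trial-to-trial drift SD s_d and
start-point range s_z; non-decision time t_ND; in the bias condition an
extra cued start point z_cue. RT = first-passage time + t_ND.

Because the full DDM has no closed-form likelihood, fits use the
probability density approximation (PDA): large synthetic samples from the
model are kernel-smoothed into defective RT densities and evaluated at the
observed data. Posteriors are sampled with differential-evolution MCMC
(crossover + migration moves, noisy-likelihood-tolerant), hierarchically:
individual parameters ~ Normal group distributions per population and
instruction condition, each condition fit separately.

Bayes-factor utilities (JZS t tests, Pearson correlations, posterior
"Bayesian p values") cover the accompanying behavioral statistics.

## Worked example

```python
import numpy as np
import blastdm as b
from blastdm.demcmc import SamplerConfig, run
from blastdm.pda import PDAConfig
from blastdm.pipeline import recovery_table

# a synthetic novice cohort with known group-level parameters
hyper = b.default_novice_hyper()
profiles = b.sample_participants(hyper, 20, seed=42)
trials = b.simulate_dataset(profiles, b.ExperimentConfig(rng_seed=42),
                            model="ddm", seed=43)

# hierarchical DDM fit of the accuracy condition
acc = trials[trials.condition == "accuracy"]
draws = run(acc, "accuracy", deadline_s=5.0,
            config=SamplerConfig(n_chains=12, n_burn=150, n_keep=100, seed=7),
            pda_config=PDAConfig(n_syn=2000, dt=0.01))
print(recovery_table(draws, hyper.per_condition["accuracy"]))
```

Output (about 9 minutes on one core):

```
  parameter  truth  post_mean     ci_lo     ci_hi  covered  rel_error
0      d_be   0.18   0.189812  0.160207  0.222470     True   0.054510
1      d_bh   0.10   0.096627  0.064586  0.126639     True   0.033734
2     d_nbe  -0.22  -0.229589 -0.260944 -0.199437     True   0.043587
3     d_nbh  -0.07  -0.063506 -0.087850 -0.039666     True   0.092765
4       s_d   0.08   0.077867  0.050383  0.110995     True   0.026657
5         a   0.14   0.138142  0.129730  0.147441     True   0.013274
6     z_rel   0.50   0.502796  0.473992  0.529388     True   0.005593
7       s_z   0.02   0.019734  0.015042  0.025437     True   0.013305
8      t_nd   0.35   0.362248  0.343759  0.380993     True   0.034994
```

Each row compares a ground-truth group location with its posterior: all
nine recovered within a few percent, 95% credible intervals covering the
truth — drifts ordered easy > hard, the threshold and non-decision time
pinned tightly. A quick Bayes-factor check:

```python
>>> b.jzs_ttest_bf(t=1.47, n=34, paired=True).bf10
0.489070594524945
```

i.e. data with t(33) = 1.47 favor the null about 2:1.

A command-line interface mirrors the library:
`blastdm simulate`, `blastdm fit`, `blastdm ppc`, `blastdm recover`,
`blastdm stats ttest|corr|posterior-p` (see `--help`).

## Layout

- `src/blastdm/ddm.py` — diffusion simulator (bridge-corrected Euler) and
  analytic first-passage oracles
- `src/blastdm/pda.py` — kernel-density likelihood approximation
- `src/blastdm/demcmc.py` — differential-evolution MCMC, flat and
  hierarchical
- `src/blastdm/sdt.py` — equal-variance SDT, closed form and Bayesian
- `src/blastdm/stats.py` — Bayes factors and posterior p values
- `src/blastdm/synthetic.py` — experiment-design generator and trial I/O
- `src/blastdm/pipeline.py` — per-condition fits, posterior-predictive
  checks, recovery studies
- `docs/methods.md` — model assumptions, numerical choices, limitations
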