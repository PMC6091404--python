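"""Differential-evolution MCMC, flat and hierarchical.

Proposals are scaled differences of other chains' states,
theta* = theta_k + gamma (theta_m - theta_n) + eps, which self-tunes to the
strong parameter correlations of sequential-sampling models. A migration
move (cyclic state swaps among a random chain subset) guards against stuck
chains. The hierarchical variant alternates individual-level blocks (one
DE crossover per participant, with the group distribution as prior) and
group-level blocks (conjugate Gibbs for the group location, DE Metropolis
for the group scale).

The individual-level likelihood may be noisy (PDA). The default policy
re-evaluates the likelihood only for proposals ("resample on accept") and
refreshes all stored values every ``refresh_every`` iterations, limiting
the stuck-chain artifacts caused by lucky noisy likelihood draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class SamplerConfig:
    """Tuning knobs; defaults follow standard DE-MCMC practice."""
    n_chains: Optional[int] = None      # default 3 x dimension
    n_burn: int = 500
    n_keep: int = 500
    thin: int = 1
    gamma: Optional[float] = None       # default 2.38 / sqrt(2 D)
    gamma1_prob: float = 0.10           # prob of a gamma = 1 mode-jump move
    eps: float = 0.001                  # jitter ~ Uniform(-eps, eps)
    migration_prob: float = 0.05
    resample: str = "on_accept"         # or "every_iteration"
    refresh_every: int = 20             # full re-eval cadence (noisy only)
    seed: int = 0

    def resolve(self, dim: int) -> "SamplerConfig":
        cfg = SamplerConfig(**self.__dict__)
        if cfg.n_chains is None:
            cfg.n_chains = 3 * dim
        if cfg.n_chains < dim + 2:
            raise ValueError(f"need at least dim+2={dim + 2} chains")
        if cfg.gamma is None:
            cfg.gamma = 2.38 / np.sqrt(2.0 * dim)
        if not (0 <= cfg.migration_prob <= 1):
            raise ValueError("migration_prob must be in [0, 1]")
        if cfg.resample not in ("on_accept", "every_iteration"):
            raise ValueError("unknown resample policy")
        return cfg


@dataclass
class HyperParams:
    """Group-level location/scale per individual-level coordinate."""
    names: Tuple[str, ...]
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        if np.any(self.sigma <= 0):
            raise ValueError("hyper scales must be > 0")


# ---------------------------------------------------------------------------
# core moves

def init_chains(logpost: Callable, prior_sampler: Callable, n_chains: int,
                rng: np.random.Generator, max_retries: int = 500):
    """Overdispersed prior starts with finite log-density."""
    states = np.empty((n_chains, 0))
    rows, logps = [], []
    for k in range(n_chains):
        for _ in range(max_retries):
            x = np.atleast_1d(np.asarray(prior_sampler(rng), dtype=float))
            lp = logpost(x)
            if np.isfinite(lp):
                rows.append(x)
                logps.append(lp)
                break
        else:
            raise RuntimeError(
                f"chain {k}: no finite-density start in {max_retries} tries")
    return np.array(rows), np.array(logps)


def _pick_pair(k: int, n: int, rng) -> Tuple[int, int]:
    m = rng.integers(n - 1)
    m = m if m < k else m + 1
    while True:
        j = rng.integers(n - 1)
        j = j if j < k else j + 1
        if j != m:
            return int(m), int(j)


def crossover_step(states: np.ndarray, logps: np.ndarray,
                   logpost: Callable, gamma: float, eps: float,
                   rng: np.random.Generator,
                   gamma1_prob: float = 0.0) -> int:
    """One DE crossover sweep over all chains, in place; returns accepts."""
    n, d = states.shape
    if n < 3:
        raise ValueError("crossover needs at least 3 chains")
    n_acc = 0
    for k in range(n):
        m, j = _pick_pair(k, n, rng)
        g = 1.0 if (gamma1_prob > 0 and rng.random() < gamma1_prob) else gamma
        prop = states[k] + g * (states[m] - states[j]) \
            + rng.uniform(-eps, eps, size=d)
        lp = logpost(prop)
        if lp - logps[k] > np.log(rng.random() + 1e-300):
            states[k] = prop
            logps[k] = lp
            n_acc += 1
    return n_acc


def migration_step(states: np.ndarray, logps: np.ndarray,
                   prob: float, rng: np.random.Generator) -> int:
    """With probability ``prob``, cyclically propose state swaps among a
    random chain subset, each accepted by the Metropolis rule on stored
    log-densities. Returns number of accepted swaps."""
    n = states.shape[0]
    if n < 2 or rng.random() >= prob:
        return 0
    # small subsets: enough to rescue a stuck chain without collapsing
    # ensemble diversity through repeated state duplication
    size = int(rng.integers(2, min(n, 3) + 1))
    idx = rng.permutation(n)[:size]
    prev_states = states[idx].copy()
    prev_logps = logps[idx].copy()
    n_acc = 0
    for pos, k in enumerate(idx):
        src = pos - 1  # cyclic: chain idx[pos] receives idx[pos-1]'s state
        if prev_logps[src] - logps[k] > np.log(rng.random() + 1e-300):
            states[k] = prev_states[src]
            logps[k] = prev_logps[src]
            n_acc += 1
    return n_acc


def update_hyper(thetas: np.ndarray, current: HyperParams,
                 mu_prior: Sequence[Tuple[float, float]],
                 sigma_scale: Sequence[float],
                 rng: np.random.Generator,
                 n_mh: int = 5, mh_step: float = 0.3) -> HyperParams:
    """One group-level update given individual values (P, D).

    The hyper conditional depends on the data only through the individual
    values. Location: exact normal-normal Gibbs draw. Scale: random-walk
    Metropolis on log sigma against a half-Normal(0, sigma_scale) prior.
    """
    thetas = np.atleast_2d(thetas)
    P, D = thetas.shape
    mu = current.mu.copy()
    sigma = current.sigma.copy()
    for j in range(D):
        m0, t0 = mu_prior[j]
        v = 1.0 / (P / sigma[j] ** 2 + 1.0 / t0 ** 2)
        m = v * (thetas[:, j].sum() / sigma[j] ** 2 + m0 / t0 ** 2)
        mu[j] = rng.normal(m, np.sqrt(v))
        ls = np.log(sigma[j])
        dev2 = np.sum((thetas[:, j] - mu[j]) ** 2)

        def logp(ls_):
            s = np.exp(ls_)
            return (-P * ls_ - dev2 / (2 * s * s)
                    - s * s / (2 * sigma_scale[j] ** 2) + ls_)

        cur = logp(ls)
        for _ in range(n_mh):
            prop = ls + mh_step * rng.standard_normal()
            lp = logp(prop)
            if lp - cur > np.log(rng.random() + 1e-300):
                ls, cur = prop, lp
        sigma[j] = np.exp(ls)
    return HyperParams(current.names, mu, sigma)


# ---------------------------------------------------------------------------
# posterior containers and diagnostics

def diagnostics(draws: np.ndarray) -> Tuple[float, float]:
    """(split R-hat, effective sample size) for one (chains, iters) array,
    by the standard rank-normalized definitions (arviz)."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 50:
        raise ValueError("need >= 2 chains and >= 50 retained iterations")
    import arviz as az
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(draws)), float(az.ess(draws))


@dataclass
class PosteriorDraws:
    """MCMC output. Flat fits fill ``draws`` (chains, iters, D); the
    hierarchical fit fills ``theta`` (chains, iters, P, D) plus ``mu`` and
    ``sigma`` (chains, iters, D)."""
    param_names: Tuple[str, ...]
    draws: Optional[np.ndarray] = None
    theta: Optional[np.ndarray] = None
    mu: Optional[np.ndarray] = None
    sigma: Optional[np.ndarray] = None
    participant_ids: Optional[List[str]] = None
    accept_rate: Optional[float] = None

    def flat(self, name: str) -> np.ndarray:
        """All retained draws of one flat-level parameter, flattened."""
        j = self.param_names.index(name)
        src = self.draws if self.draws is not None else self.mu
        return src[:, :, j].ravel()

    def hyper_mu(self, name: str) -> np.ndarray:
        j = self.param_names.index(name)
        return self.mu[:, :, j].ravel()

    def diagnostics_table(self) -> pd.DataFrame:
        rows = []
        if self.draws is not None:
            for j, nm in enumerate(self.param_names):
                r, e = diagnostics(self.draws[:, :, j])
                rows.append((nm, r, e))
        else:
            for j, nm in enumerate(self.param_names):
                r, e = diagnostics(self.mu[:, :, j])
                rows.append((f"mu_{nm}", r, e))
                r, e = diagnostics(self.sigma[:, :, j])
                rows.append((f"sigma_{nm}", r, e))
        return pd.DataFrame(rows, columns=["parameter", "rhat", "ess"])

    def summary(self) -> pd.DataFrame:
        rows = []

        def add(nm, x):
            lo, hi = np.percentile(x, [2.5, 97.5])
            rows.append((nm, float(np.mean(x)), float(np.std(x)), lo, hi))

        if self.draws is not None:
            for j, nm in enumerate(self.param_names):
                add(nm, self.draws[:, :, j])
        else:
            for j, nm in enumerate(self.param_names):
                add(f"mu_{nm}", self.mu[:, :, j])
                add(f"sigma_{nm}", self.sigma[:, :, j])
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd",
                                           "ci_lo", "ci_hi"])

    def to_long_dataframe(self) -> pd.DataFrame:
        """Long format (chain, iteration, level, participant, parameter,
        value) for CSV export."""
        recs = []
        if self.draws is not None:
            C, I, D = self.draws.shape
            for j, nm in enumerate(self.param_names):
                for c in range(C):
                    for t in range(I):
                        recs.append((c, t, "flat", "", nm,
                                     self.draws[c, t, j]))
        else:
            C, I, P, D = self.theta.shape
            ids = self.participant_ids or [str(i) for i in range(P)]
            for j, nm in enumerate(self.param_names):
                for c in range(C):
                    for t in range(I):
                        recs.append((c, t, "hyper_mu", "", nm,
                                     self.mu[c, t, j]))
                        recs.append((c, t, "hyper_sigma", "", nm,
                                     self.sigma[c, t, j]))
                        for p in range(P):
                            recs.append((c, t, "individual", ids[p], nm,
                                         self.theta[c, t, p, j]))
        return pd.DataFrame(recs, columns=["chain", "iteration", "level",
                                           "participant", "parameter",
                                           "value"])


# ---------------------------------------------------------------------------
# generic sampler (tractable targets, flat fits)

def sample(logpost: Callable, dim: int, prior_sampler: Callable,
           config: SamplerConfig,
           param_names: Optional[Sequence[str]] = None) -> PosteriorDraws:
    """DE-MCMC on an arbitrary target; returns retained draws."""
    cfg = config.resolve(dim)
    rng = np.random.default_rng(cfg.seed)
    states, logps = init_chains(logpost, prior_sampler, cfg.n_chains, rng)
    n_iter = cfg.n_burn + cfg.n_keep * cfg.thin
    kept = np.empty((cfg.n_chains, cfg.n_keep, dim))
    n_acc = 0
    n_prop = 0
    ptr = 0
    for it in range(n_iter):
        n_acc += crossover_step(states, logps, logpost, cfg.gamma, cfg.eps,
                                rng, cfg.gamma1_prob)
        n_prop += cfg.n_chains
        migration_step(states, logps, cfg.migration_prob, rng)
        if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thin == 0:
            kept[:, ptr, :] = states
            ptr += 1
    names = tuple(param_names) if param_names else \
        tuple(f"p{j}" for j in range(dim))
    return PosteriorDraws(param_names=names, draws=kept[:, :ptr, :],
                          accept_rate=n_acc / n_prop)


# ---------------------------------------------------------------------------
# hierarchical sampler

@dataclass
class HierarchicalFit:
    """Hierarchical DE-MCMC: individual coordinates theta_i ~ Normal(mu,
    sigma) component-wise on the sampling scale, arbitrary (possibly noisy)
    likelihood per participant.

    loglik(i, theta, seed) must return the log-likelihood of participant
    i's data; ``seed`` drives fresh synthetic draws when ``noisy``.
    """
    loglik: Callable[[int, np.ndarray, int], float]
    n_participants: int
    param_names: Tuple[str, ...]
    mu_prior: Sequence[Tuple[float, float]]     # (m0, tau0) per coordinate
    sigma_scale: Sequence[float]                # half-Normal scale per coord
    config: SamplerConfig = field(default_factory=SamplerConfig)
    theta_init_scale: Optional[Sequence[float]] = None
    noisy: bool = True
    fixed_sigma: Optional[Sequence[float]] = None
    #: optional (P, D) data-driven starting vectors; chains start scattered
    #: around them instead of around the hyper-prior location
    init_vectors: Optional[np.ndarray] = None
    progress: bool = False

    def run(self, participant_ids: Optional[List[str]] = None
            ) -> PosteriorDraws:
        D = len(self.param_names)
        P = self.n_participants
        cfg = self.config.resolve(D)
        rng = np.random.default_rng(cfg.seed)
        m0 = np.array([m for m, _ in self.mu_prior])
        t0 = np.array([t for _, t in self.mu_prior])
        init_sd = np.array(self.theta_init_scale) if self.theta_init_scale \
            is not None else np.minimum(t0, 1.0)
        K = cfg.n_chains

        iv = None
        if self.init_vectors is not None:
            iv = np.asarray(self.init_vectors, dtype=float)
            if iv.shape != (P, D):
                raise ValueError("init_vectors must be (participants, dim)")
        mu = np.empty((K, D))
        sigma = np.empty((K, D))
        theta = np.empty((K, P, D))
        llik = np.empty((K, P))
        for k in range(K):
            if iv is not None:
                mu[k] = iv.mean(axis=0) + 0.3 * init_sd * \
                    rng.standard_normal(D)
            else:
                mu[k] = rng.normal(m0, t0 * 0.5)
            sigma[k] = (np.asarray(self.fixed_sigma, dtype=float)
                        if self.fixed_sigma is not None
                        else np.abs(rng.normal(0, self.sigma_scale)) + 0.02)
            for i in range(P):
                for attempt in range(500):
                    # widen/recentre progressively if draws keep landing
                    # outside the likelihood's support
                    if iv is not None:
                        center = iv[i] if attempt < 100 else mu[k]
                        spread = 0.3 * init_sd
                    else:
                        center = mu[k] if attempt < 100 else m0
                        spread = init_sd
                    cand = center + spread * rng.standard_normal(D)
                    ll = self.loglik(i, cand, int(rng.integers(2**31 - 1)))
                    if np.isfinite(ll):
                        theta[k, i] = cand
                        llik[k, i] = ll
                        break
                else:
                    raise RuntimeError(
                        f"participant {i}: no finite-likelihood start")

        gamma = cfg.gamma
        n_iter = cfg.n_burn + cfg.n_keep * cfg.thin
        kept_theta = np.empty((K, cfg.n_keep, P, D))
        kept_mu = np.empty((K, cfg.n_keep, D))
        kept_sigma = np.empty((K, cfg.n_keep, D))
        ptr = 0
        n_acc = 0
        n_prop = 0
        log = np.log

        def gprior(th, k):
            # component-wise normal group density
            return float(np.sum(-0.5 * ((th - mu[k]) / sigma[k]) ** 2
                                - log(sigma[k])))

        for it in range(n_iter):
            # --- individual blocks
            for i in range(P):
                for k in range(K):
                    m, j = _pick_pair(k, K, rng)
                    g = 1.0 if rng.random() < cfg.gamma1_prob else gamma
                    prop = theta[k, i] + g * (theta[m, i] - theta[j, i]) \
                        + rng.uniform(-cfg.eps, cfg.eps, size=D)
                    ll_prop = self.loglik(i, prop,
                                          int(rng.integers(2**31 - 1)))
                    if self.noisy and cfg.resample == "every_iteration":
                        llik[k, i] = self.loglik(
                            i, theta[k, i], int(rng.integers(2**31 - 1)))
                    num = ll_prop + gprior(prop, k)
                    den = llik[k, i] + gprior(theta[k, i], k)
                    n_prop += 1
                    if num - den > log(rng.random() + 1e-300):
                        theta[k, i] = prop
                        llik[k, i] = ll_prop
                        n_acc += 1
                # migration across chains for this participant
                if rng.random() < cfg.migration_prob and K >= 2:
                    size = int(rng.integers(2, min(K, 3) + 1))
                    idx = rng.permutation(K)[:size]
                    prev_t = theta[idx, i].copy()
                    prev_l = llik[idx, i].copy()
                    for pos, k in enumerate(idx):
                        src = pos - 1
                        num = prev_l[src] + gprior(prev_t[src], k)
                        den = llik[k, i] + gprior(theta[k, i], k)
                        if num - den > log(rng.random() + 1e-300):
                            theta[k, i] = prev_t[src]
                            llik[k, i] = prev_l[src]
            # --- periodic full likelihood refresh (noisy likelihoods)
            if self.noisy and cfg.resample == "on_accept" \
                    and cfg.refresh_every > 0 \
                    and (it + 1) % cfg.refresh_every == 0:
                for k in range(K):
                    for i in range(P):
                        llik[k, i] = self.loglik(
                            i, theta[k, i], int(rng.integers(2**31 - 1)))
            # --- hyper blocks (cheap; data enter only through theta)
            for k in range(K):
                hp = update_hyper(
                    theta[k], HyperParams(self.param_names, mu[k].copy(),
                                          sigma[k].copy()),
                    self.mu_prior, self.sigma_scale, rng,
                    n_mh=0 if self.fixed_sigma is not None else 3)
                mu[k] = hp.mu
                if self.fixed_sigma is None:
                    sigma[k] = hp.sigma
            if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thin == 0:
                kept_theta[:, ptr] = theta
                kept_mu[:, ptr] = mu
                kept_sigma[:, ptr] = sigma
                ptr += 1
            if self.progress and (it + 1) % 25 == 0:
                print(f"  iter {it + 1}/{n_iter} "
                      f"acc={n_acc / max(n_prop, 1):.2f}", flush=True)
        return PosteriorDraws(
            param_names=self.param_names,
            theta=kept_theta[:, :ptr], mu=kept_mu[:, :ptr],
            sigma=kept_sigma[:, :ptr],
            participant_ids=participant_ids,
            accept_rate=n_acc / max(n_prop, 1))


# ---------------------------------------------------------------------------
# DDM-specific entry point

def ez_starting_point(trials: pd.DataFrame, deadline_s: float,
                      s: float = 0.1) -> dict:
    """Closed-form moment-matching starting values for one participant.

    EZ-style inversion per stimulus cell: accuracy plus mean/variance of
    RT give drift magnitude, threshold, and non-decision time under the
    no-variability, unbiased submodel. Only used to seed chains near the
    data-supported region; the posterior is unaffected.
    """
    cells = {}
    for (stim, diff), cell in trials.groupby(["stimulus", "difficulty"],
                                             observed=True):
        n = len(cell)
        if n < 5:
            continue
        p = float((cell["choice"] == stim).mean())
        p = float(np.clip(p, 0.5 + 1.0 / (2 * n), 1 - 1.0 / (2 * n)))
        rt = cell["rt_s"].to_numpy(dtype=float)
        mrt = float(np.mean(rt))
        vrt = max(float(np.var(rt, ddof=1)), 1e-4)
        L = np.log(p / (1 - p))
        x = L * (L * p * p - L * p + p - 0.5) / vrt
        v = s * x ** 0.25
        a = s * s * L / v
        ka = v * a / (s * s)
        mdt = (a / (2 * v)) * (1 - np.exp(-ka)) / (1 + np.exp(-ka))
        cells[(stim, diff)] = (v, a, mrt - mdt)
    if not cells:
        raise ValueError("not enough trials for starting values")
    a0 = float(np.median([c[1] for c in cells.values()]))
    a0 = float(np.clip(a0, 0.02, 1.0))
    rt_min = float(trials["rt_s"].min())
    t0 = float(np.median([c[2] for c in cells.values()]))
    t0 = float(np.clip(t0, 0.05, max(0.9 * rt_min, 0.051)))
    out = {"a": a0, "t_nd": t0, "z_rel": 0.5, "z_cue_rel": 0.55,
           "s_d": 0.05, "s_z": min(0.02, 0.2 * a0)}
    for (stim, diff), (v, _, _) in cells.items():
        key = {"blast": "d_b", "nonblast": "d_nb"}[stim] + diff[0]
        out[key] = v if stim == "blast" else -v
    # fall back to small drifts for cells that could not be estimated
    for key in ("d_be", "d_bh", "d_nbe", "d_nbh"):
        out.setdefault(key, 0.05 if "nb" not in key else -0.05)
    return out


def _ez_vector(trials, deadline_s, names):
    from .ddm import DDMParams
    from .transforms import params_to_vector
    ez = ez_starting_point(trials, deadline_s)
    p = DDMParams(d_be=ez["d_be"], d_bh=ez["d_bh"], d_nbe=ez["d_nbe"],
                  d_nbh=ez["d_nbh"], s_d=ez["s_d"], a=ez["a"],
                  z=ez["z_rel"] * ez["a"], s_z=ez["s_z"], t_nd=ez["t_nd"],
                  z_cue=ez["z_cue_rel"] * ez["a"]
                  if "logit_z_cue" in names else None)
    return params_to_vector(p, names)

#: default priors for the group locations on the sampling scale
DDM_MU_PRIOR = {
    "d_be": (0.0, 2.0), "d_bh": (0.0, 2.0),
    "d_nbe": (0.0, 2.0), "d_nbh": (0.0, 2.0),
    "log_s_d": (np.log(0.08), 1.0),
    "log_a": (np.log(0.15), 0.8),
    "logit_z": (0.0, 1.0),
    "log_s_z": (np.log(0.02), 1.0),
    "log_t_nd": (np.log(0.3), 0.6),
    "logit_z_cue": (0.0, 1.0),
}
DDM_SIGMA_SCALE = 0.5
#: tighter initial spread than the prior, so prior-drawn chains start in a
#: physically sensible region (still overdispersed relative to posteriors)
DDM_INIT_SCALE = {
    "d_be": 0.3, "d_bh": 0.3, "d_nbe": 0.3, "d_nbh": 0.3,
    "log_s_d": 0.5, "log_a": 0.4, "logit_z": 0.4, "log_s_z": 0.5,
    "log_t_nd": 0.3, "logit_z_cue": 0.4,
}


def run(trials: pd.DataFrame, condition: str, deadline_s: float,
        config: Optional[SamplerConfig] = None,
        pda_config=None, hard_only: bool = False,
        strict: bool = False) -> PosteriorDraws:
    """Hierarchical DDM fit of one instruction condition, one population.

    ``trials`` must already be filtered to the condition and population;
    timeouts are excluded here. ``hard_only`` drops easy-cell trials and
    the corresponding drifts (the pathologist accuracy-condition rule).
    The bias condition activates z_cue and fits cued and uncued trials
    jointly.
    """
    from .pda import PDAConfig, pda_loglik
    from .transforms import param_names as _names, vector_to_params

    pda_config = pda_config or PDAConfig()
    config = config or SamplerConfig()
    names = _names(condition, hard_only=hard_only)
    t = trials[trials["choice"] != "timeout"]
    if hard_only:
        t = t[t["difficulty"] == "hard"]
    pids = sorted(t["participant_id"].unique())
    if not pids:
        raise ValueError("no usable trials")
    per_p = {pid: t[t["participant_id"] == pid].reset_index(drop=True)
             for pid in pids}

    def loglik(i, vec, seed):
        params = vector_to_params(vec, names)
        return pda_loglik(params, per_p[pids[i]], deadline_s,
                          pda_config, seed)

    init_vectors = np.array([_ez_vector(per_p[pid], deadline_s, names)
                             for pid in pids])
    fit = HierarchicalFit(
        loglik=loglik, n_participants=len(pids), param_names=names,
        mu_prior=[DDM_MU_PRIOR[n] for n in names],
        sigma_scale=[DDM_SIGMA_SCALE] * len(names),
        theta_init_scale=[DDM_INIT_SCALE[n] for n in names],
        config=config, noisy=True, init_vectors=init_vectors)
    draws = fit.run(participant_ids=pids)
    if strict:
        bad = draws.diagnostics_table().query("rhat > 1.1")
        if len(bad):
            raise RuntimeError(f"non-converged parameters:\n{bad}")
    return draws
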