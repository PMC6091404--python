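"""Equal-variance signal detection theory, flat and hierarchical.

Blast is the signal class. With discriminability d' and criterion c
(measured from the midpoint of the two unit-variance normals, so negative c
is a liberal, blast-favoring bias):

    hit rate        h = Phi(d'/2 - c)
    false-alarm     f = Phi(-d'/2 - c)

and inversely d' = Phi^-1(h) - Phi^-1(f), c = -(Phi^-1(h) + Phi^-1(f))/2.

Hierarchical fits put Normal group distributions on (d'_i, c_i) per
experience group and condition (and per cue state in bias blocks), with a
binomial likelihood, sampled by the shared DEMCMC machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import log_ndtr, ndtr, ndtri

COUNT_COLUMNS = ["participant_id", "group", "condition", "cue",
                 "hits", "misses", "false_alarms", "correct_rejections"]


@dataclass
class SDTParams:
    d_prime: float
    c: float


def sdt_rates(params: SDTParams):
    """(hit probability, false-alarm probability)."""
    h = float(ndtr(params.d_prime / 2.0 - params.c))
    f = float(ndtr(-params.d_prime / 2.0 - params.c))
    return h, f


def dprime_closed_form(hits: int, misses: int, false_alarms: int,
                       correct_rejections: int,
                       correct: bool = True) -> SDTParams:
    """Closed-form estimate from counts, the oracle for the Bayesian fit.

    With ``correct`` a 0.5/(n+1)-style continuity correction keeps rates off
    0 and 1 (applied only when needed).
    """
    n_sig = hits + misses
    n_noise = false_alarms + correct_rejections
    if n_sig == 0 or n_noise == 0:
        raise ValueError("need at least one signal and one noise trial")

    def rate(k, n):
        r = k / n
        if correct and (k == 0 or k == n):
            r = (k + 0.5) / (n + 1)
        if not (0 < r < 1):
            raise ValueError("rate on the boundary; enable the continuity "
                             "correction")
        return r

    h = rate(hits, n_sig)
    f = rate(false_alarms, n_noise)
    zh, zf = ndtri(h), ndtri(f)
    return SDTParams(d_prime=float(zh - zf), c=float(-(zh + zf) / 2.0))


def counts_from_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Tally hits/misses/false alarms/correct rejections per participant x
    condition (x cue state in bias blocks). Timeouts are excluded. Cells
    with zero trials for a participant are omitted with a warning."""
    t = trials[trials["choice"] != "timeout"].copy()
    t["cue"] = np.where(t["condition"] == "bias", t["cue"], "none")
    rows = []
    group_by_pid = (trials.groupby("participant_id")
                    .agg(population=("population", "first"),
                         experience=("experience", "first")))
    for (pid, cond, cue), sub in t.groupby(
            ["participant_id", "condition", "cue"], observed=True):
        blast = sub["stimulus"] == "blast"
        said_blast = sub["choice"] == "blast"
        if blast.sum() == 0 or (~blast).sum() == 0:
            warnings.warn(f"participant {pid}, {cond}/{cue}: empty stimulus "
                          "class; cell omitted")
            continue
        info = group_by_pid.loc[pid]
        grp = info["population"] if info["population"] == "novice" or \
            not info["experience"] else info["experience"]
        rows.append((pid, grp, cond, cue,
                     int((blast & said_blast).sum()),
                     int((blast & ~said_blast).sum()),
                     int((~blast & said_blast).sum()),
                     int((~blast & ~said_blast).sum())))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


# ---------------------------------------------------------------------------
# Bayesian fits (shared DEMCMC sampler)

def _binom_loglik(theta: np.ndarray, hits, n_sig, fa, n_noise) -> float:
    d, c = theta
    lh = log_ndtr(d / 2.0 - c)
    lmiss = log_ndtr(c - d / 2.0)
    lf = log_ndtr(-d / 2.0 - c)
    lcr = log_ndtr(d / 2.0 + c)
    return float(hits * lh + (n_sig - hits) * lmiss
                 + fa * lf + (n_noise - fa) * lcr)


def fit_sdt_single(hits: int, misses: int, false_alarms: int,
                   correct_rejections: int, seed: int = 0,
                   n_chains: int = 8, n_burn: int = 300, n_keep: int = 500):
    """Flat-prior fit of one participant's counts; returns PosteriorDraws
    over (d_prime, c). Converges to the closed-form estimate at large n."""
    from .demcmc import SamplerConfig, sample
    n_sig = hits + misses
    n_noise = false_alarms + correct_rejections

    def logpost(th):
        if abs(th[0]) > 10 or abs(th[1]) > 10:
            return -np.inf
        return _binom_loglik(th, hits, n_sig, false_alarms, n_noise)

    cfg = SamplerConfig(n_chains=n_chains, n_burn=n_burn, n_keep=n_keep,
                        seed=seed)
    rng = np.random.default_rng(seed)
    init = lambda r: np.array([r.normal(1.0, 1.0), r.normal(0.0, 0.5)])
    return sample(logpost, 2, init, cfg, param_names=("d_prime", "c"))


def fit_hierarchical_sdt(counts: pd.DataFrame, condition: str,
                         cue: str = "none",
                         grouping: Optional[Dict[str, str]] = None,
                         seed: int = 0, n_chains: int = 12,
                         n_burn: int = 400, n_keep: int = 400) -> Dict:
    """Hierarchical fit per experience group for one condition (and cue
    state in bias). Individual (d'_i, c_i) ~ Normal(mu, sigma) per group;
    binomial likelihood; DEMCMC. Returns {group: PosteriorDraws}."""
    from .demcmc import HierarchicalFit, SamplerConfig

    sub = counts[(counts["condition"] == condition) & (counts["cue"] == cue)]
    if grouping is not None:
        sub = sub.assign(group=sub["participant_id"].map(grouping))
    results = {}
    for grp, block in sub.groupby("group", observed=True):
        if len(block) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 participants")
        data = [(int(r.hits), int(r.hits + r.misses), int(r.false_alarms),
                 int(r.false_alarms + r.correct_rejections))
                for r in block.itertuples()]

        def loglik(i, theta, seed_unused, _data=data):
            if abs(theta[0]) > 10 or abs(theta[1]) > 10:
                return -np.inf
            h, ns, f, nn = _data[i]
            return _binom_loglik(theta, h, ns, f, nn)

        cfg = SamplerConfig(n_chains=n_chains, n_burn=n_burn, n_keep=n_keep,
                            seed=seed)
        fit = HierarchicalFit(
            loglik=loglik, n_participants=len(data),
            param_names=("d_prime", "c"),
            mu_prior=((0.0, 3.0), (0.0, 3.0)),
            sigma_scale=(1.0, 1.0),
            theta_init_scale=(1.0, 0.5),
            config=cfg, noisy=False)
        results[grp] = fit.run(
            participant_ids=list(block["participant_id"]))
    return results
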