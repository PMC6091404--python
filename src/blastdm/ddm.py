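"""Diffusion decision model core.

Two-boundary Wiener accumulator for blast / non-blast decisions. Evidence
starts at ``z`` and drifts at a stimulus-dependent rate until it is absorbed
at the upper boundary ``a`` ("blast") or the lower boundary 0 ("non-blast").
Trial-to-trial variability: drift is Normal(mean drift, s_d) and the start
point is Uniform(z - s_z/2, z + s_z/2). Within-trial noise is fixed at
s = 0.1 to resolve the model's scale degeneracy.

The module provides a fast stochastic simulator (Euler scheme with a
Brownian-bridge absorption correction, so coarse steps remain accurate) and
two analytic oracles for the no-variability submodel (s_d = s_z = 0): the
closed-form absorption probability and the classical series solution for the
first-passage-time density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from ._kernels import simulate_cell_kernel

#: within-trial diffusion coefficient, fixed by convention (not a free parameter)
NOISE_S = 0.1

BLAST = "blast"
NONBLAST = "nonblast"
EASY = "easy"
HARD = "hard"


@dataclass
class DDMParams:
    """Per-participant diffusion parameters for one instruction condition.

    Drift rates are signed: blast drifts (``d_be``, ``d_bh``) are expected
    positive, non-blast drifts (``d_nbe``, ``d_nbh``) negative; no sign is
    imposed by code. ``z_cue`` is the alternative mean start point used on
    cue-present trials of the bias condition (None elsewhere).
    """

    d_be: float
    d_bh: float
    d_nbe: float
    d_nbh: float
    s_d: float
    a: float
    z: float
    s_z: float
    t_nd: float
    z_cue: Optional[float] = None
    s: float = field(default=NOISE_S)

    def validate(self) -> None:
        if not math.isclose(self.s, NOISE_S):
            raise ValueError(f"within-trial noise s is fixed at {NOISE_S}")
        vals = [self.d_be, self.d_bh, self.d_nbe, self.d_nbh,
                self.s_d, self.a, self.z, self.s_z, self.t_nd]
        if self.z_cue is not None:
            vals.append(self.z_cue)
        if not all(np.isfinite(vals)):
            raise ValueError("non-finite DDM parameter")
        if self.a <= 0:
            raise ValueError("threshold separation a must be > 0")
        if self.s_d < 0 or self.s_z < 0 or self.t_nd < 0:
            raise ValueError("s_d, s_z, t_nd must be >= 0")
        for name, zz in (("z", self.z), ("z_cue", self.z_cue)):
            if zz is None:
                continue
            if not (zz - self.s_z / 2 > 0 and zz + self.s_z / 2 < self.a):
                raise ValueError(
                    f"start point {name}={zz} with range s_z={self.s_z} "
                    f"must stay inside (0, a={self.a})")

    def is_valid(self) -> bool:
        try:
            self.validate()
        except ValueError:
            return False
        return True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DDMParams":
        return cls(**d)


def drift_for_stimulus(params: DDMParams, stimulus: str, difficulty: str) -> float:
    """Mean drift for one stimulus cell; signs live in the parameter values."""
    table = {
        (BLAST, EASY): params.d_be,
        (BLAST, HARD): params.d_bh,
        (NONBLAST, EASY): params.d_nbe,
        (NONBLAST, HARD): params.d_nbh,
    }
    try:
        return table[(stimulus, difficulty)]
    except KeyError:
        raise ValueError(f"unknown stimulus cell ({stimulus!r}, {difficulty!r})")


def analytic_choice_probability(v: float, a: float, z: float, s: float = NOISE_S) -> float:
    """P(absorb at upper boundary) for a drift-diffusion with no trial variability.

    (1 - exp(-2 v z / s^2)) / (1 - exp(-2 v a / s^2)); continuous limit z/a at v = 0.
    """
    if a <= 0 or not (0 < z < a) or s <= 0:
        raise ValueError("require a > 0, 0 < z < a, s > 0")
    k = 2.0 * v / (s * s)
    if abs(k * a) < 1e-9:
        return z / a
    if k < 0 and -k * a > 700:          # strongly negative drift
        return float(np.exp(-(-k) * (a - z)))
    return float(np.expm1(-k * z) / np.expm1(-k * a))


def _fpt_density_lower_unit(t: float, v: float, a: float, w: float,
                            tol: float, max_terms: int) -> float:
    """Defective FPT density at the lower boundary, sigma = 1 units.

    w = z/a is the relative start point. Uses the small-time or large-time
    series expansion, switching by the standard crossover rule, truncated
    adaptively to absolute tolerance ``tol``.
    """
    if t <= 0:
        return 0.0
    # common exponential prefactor exp(-v a w - v^2 t / 2)
    lead = math.exp(-v * a * w - 0.5 * v * v * t)
    if lead == 0.0:
        return 0.0
    ts = t / (a * a)  # scaled time
    # crossover: small-time series converges fast for ts small
    if ts < 0.25:
        # f = lead * a^{-2} * ts^{-3/2}/sqrt(2 pi) * sum_k (w+2k) exp(-(w+2k)^2/(2 ts))
        acc = 0.0
        for k in range(max_terms):
            done = True
            for sign_k in ((k,) if k == 0 else (k, -k)):
                u = w + 2.0 * sign_k
                term = u * math.exp(-u * u / (2.0 * ts))
                acc += term
                if abs(term) > tol * ts ** 1.5:
                    done = False
            if k > 0 and done:
                break
        else:
            raise RuntimeError("small-time series did not reach tolerance")
        return lead / (a * a) * acc / math.sqrt(2.0 * math.pi * ts ** 3)
    # large-time series
    acc = 0.0
    for k in range(1, max_terms + 1):
        term = k * math.exp(-k * k * math.pi * math.pi * ts / 2.0) * \
            math.sin(k * math.pi * w)
        acc += term
        if k > 2 and abs(term) < tol:
            break
    else:
        raise RuntimeError("large-time series did not reach tolerance")
    return lead * math.pi / (a * a) * acc


def analytic_fpt_density(t, boundary: str, v: float, a: float, z: float,
                         s: float = NOISE_S, tol: float = 1e-8,
                         max_terms: int = 500):
    """Defective first-passage density (decision time, no t_nd shift).

    ``boundary`` is "upper" (blast) or "lower" (non-blast). Defective:
    integrating over t and summing the two boundaries gives 1. Valid for the
    no-variability submodel s_d = s_z = 0.
    """
    if a <= 0 or not (0 < z < a) or s <= 0:
        raise ValueError("require a > 0, 0 < z < a, s > 0")
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    # reduce to sigma = 1 by rescaling evidence space
    v1, a1, z1 = v / s, a / s, z / s
    if boundary == "upper":
        v1, z1 = -v1, a1 - z1
    w = z1 / a1
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.array([_fpt_density_lower_unit(float(ti), v1, a1, w, tol, max_terms)
                    for ti in tt])
    out = np.maximum(out, 0.0)
    return out if np.ndim(t) else float(out[0])


@dataclass
class FirstPassageSample:
    boundary: str            # "upper" | "lower"
    decision_time_s: float
    rt_s: float              # decision_time_s + t_nd


def sample_first_passage(mean_drift: float, params: DDMParams,
                         cue_present: bool = False,
                         rng: Optional[np.random.Generator] = None,
                         dt: float = 0.001,
                         max_time: float = 20.0) -> FirstPassageSample:
    """Draw one (boundary, RT) pair with full trial-to-trial variability.

    Trial drift ~ Normal(mean_drift, s_d); start ~ Uniform(z* +- s_z/2) with
    z* = z_cue on cue-present trials. Path absorbed at 0 or a; a trial not
    absorbed by ``max_time`` raises (callers that model deadlines pass a
    finite cap and handle timeouts themselves via :func:`simulate_trials`).
    """
    params.validate()
    if cue_present and params.z_cue is None:
        raise ValueError("cue_present requires z_cue")
    rng = np.random.default_rng() if rng is None else rng
    seed = int(rng.integers(0, 2**31 - 1))
    rts, upper = simulate_cell_kernel(
        mean_drift, params.s_d, params.a,
        params.z_cue if cue_present else params.z, params.s_z,
        params.s, dt, max_time, 1, seed)
    if not np.isfinite(rts[0]):
        raise RuntimeError(f"no absorption within {max_time} s")
    dtime = float(rts[0])
    return FirstPassageSample(
        boundary="upper" if upper[0] else "lower",
        decision_time_s=dtime, rt_s=dtime + params.t_nd)


def simulate_trials(params: DDMParams, skeletons, seed: int,
                    dt: float = 0.001, max_time: float = 20.0):
    """Vectorized simulation of (boundary, rt_s) for a list of trial skeletons.

    ``skeletons`` is an iterable of (stimulus, difficulty, cue_present)
    triples or a DataFrame with columns stimulus/difficulty/cue. Returns a
    record array with fields ``boundary`` (1 upper / 0 lower / -1 timeout)
    and ``rt_s`` (np.inf for unabsorbed trials). Deterministic given seed.
    """
    params.validate()
    import pandas as pd
    if isinstance(skeletons, pd.DataFrame):
        trips = list(zip(skeletons["stimulus"], skeletons["difficulty"],
                         (skeletons["cue"] == "present")))
    else:
        trips = [(s, d, bool(c)) for s, d, c in skeletons]
    n = len(trips)
    boundary = np.full(n, -1, dtype=np.int8)
    rt = np.full(n, np.inf)
    if n == 0:
        return np.rec.fromarrays([boundary, rt], names=["boundary", "rt_s"])
    rng = np.random.default_rng(seed)
    # group by (stimulus cell, cue state) so each group is one kernel call
    keys = {}
    for i, trip in enumerate(trips):
        keys.setdefault(trip, []).append(i)
    for (stim, diff, cue), idx in sorted(keys.items()):
        v = drift_for_stimulus(params, stim, diff)
        if cue and params.z_cue is None:
            raise ValueError("cue-present skeleton but params.z_cue is None")
        z_star = params.z_cue if cue else params.z
        sub_seed = int(rng.integers(0, 2**31 - 1))
        rts, upp = simulate_cell_kernel(
            v, params.s_d, params.a, z_star, params.s_z, params.s,
            dt, max_time, len(idx), sub_seed)
        ii = np.asarray(idx)
        fin = np.isfinite(rts)
        boundary[ii[fin]] = upp[fin]
        rt[ii[fin]] = rts[fin] + params.t_nd
    return np.rec.fromarrays([boundary, rt], names=["boundary", "rt_s"])
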