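"""Probability density approximation (PDA) likelihood.

The diffusion model with trial-to-trial variability has no closed-form
likelihood. PDA estimates it by simulating a large synthetic sample from
the model at the proposed parameters, kernel-smoothing the synthetic RTs
into one defective density per response option (Gaussian kernel, Silverman
bandwidth, mixture weight = the option's choice proportion), and evaluating
the observed (choice, RT) pairs against it. The estimate is noisy; the
sampler is configured to tolerate that (see demcmc).

Densities are conditioned on the decision finishing before the condition
deadline: simulated timeouts are dropped and the two options' weights are
renormalized over non-timeouts, mirroring the exclusion of observed
timeouts from the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .ddm import DDMParams, drift_for_stimulus
from ._kernels import simulate_cell_kernel, binned_kde_logpdf, pda_cell_loglik

DENSITY_FLOOR = 1e-10
BANDWIDTH_FLOOR = 1e-4

#: documented tolerance for KDE vs the analytic series solution: mean
#: absolute error of the defective density on an RT grid, at n_syn = 1e5
#: with s_d = s_z = 0 (bandwidth bias at the sharp post-t_nd onset dominates)
KDE_TOLERANCE = 0.05


@dataclass
class PDAConfig:
    """Numerical settings of the PDA likelihood.

    n_syn: synthetic trials per design cell per evaluation.
    dt: simulator step (bridge-corrected Euler, so coarse steps stay exact
        for the within-step dynamics; see ddm module).
    n_bins: histogram resolution used to accelerate the KDE evaluation;
        bin widths are far below the bandwidth, so the binning error is
        negligible (covered by the oracle-equivalence test).
    """
    n_syn: int = 10_000
    dt: float = 0.005
    floor: float = DENSITY_FLOOR
    n_bins: int = 256


def silverman_bandwidth(sample) -> float:
    """0.9 * min(SD, IQR/1.34) * n^(-1/5), floored at 1e-4 s."""
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("bandwidth needs at least 2 points")
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    h = 0.9 * min(sd, iqr / 1.34) * x.size ** (-0.2)
    if h < BANDWIDTH_FLOOR:
        warnings.warn("degenerate sample spread; bandwidth floored at 1e-4 s")
        return BANDWIDTH_FLOOR
    return h


@dataclass
class DefectiveDensityEstimate:
    """Kernel-smoothed defective RT densities for the two response options.

    samples: full-RT (decision + t_nd) synthetic draws per option key
    ("upper"/"lower"); weights are choice proportions among non-timeouts.
    """
    samples: Dict[str, np.ndarray]
    weights: Dict[str, float]
    bandwidths: Dict[str, float]
    floor: float = DENSITY_FLOOR

    def density(self, rt, option: str):
        """weight * KDE density at rt; floored; option may be absent."""
        rt = np.asarray(rt, dtype=float)
        scalar = rt.ndim == 0
        rt = np.atleast_1d(rt)
        samp = self.samples.get(option)
        if samp is None or samp.size < 2:
            out = np.full(rt.shape, self.floor)
        else:
            h = self.bandwidths[option]
            u = (rt[:, None] - samp[None, :]) / h
            dens = self.weights[option] * np.exp(-0.5 * u * u).sum(axis=1) \
                / (samp.size * h * np.sqrt(2 * np.pi))
            out = np.maximum(dens, self.floor)
        return float(out[0]) if scalar else out


def build_defective_density(params: DDMParams, stimulus: str, difficulty: str,
                            cue_present: bool, deadline_s: float,
                            config: Optional[PDAConfig] = None,
                            seed: int = 0) -> DefectiveDensityEstimate:
    """Simulate one design cell and assemble its defective density estimate."""
    config = config or PDAConfig()
    params.validate()
    v = drift_for_stimulus(params, stimulus, difficulty)
    z_star = params.z_cue if cue_present else params.z
    if cue_present and z_star is None:
        raise ValueError("cue-present cell requires z_cue")
    max_dec = max(deadline_s - params.t_nd, 0.0)
    rts, upper = simulate_cell_kernel(
        v, params.s_d, params.a, z_star, params.s_z, params.s,
        config.dt, max_dec, config.n_syn, seed)
    ok = np.isfinite(rts)
    n_ok = int(ok.sum())
    samples, weights, bandwidths = {}, {}, {}
    for opt, flag in (("lower", 0), ("upper", 1)):
        sel = ok & (upper == flag)
        samp = rts[sel] + params.t_nd
        if samp.size >= 2:
            samples[opt] = samp
            weights[opt] = samp.size / n_ok
            bandwidths[opt] = silverman_bandwidth(samp)
    return DefectiveDensityEstimate(samples, weights, bandwidths, config.floor)


def kde_defective_density(estimate: DefectiveDensityEstimate, rt, option: str):
    return estimate.density(rt, option)


def _cell_seed(seed: int, k: int) -> int:
    # cheap deterministic per-cell stream split
    return int((np.uint64(seed) * np.uint64(2654435761) + np.uint64(k * 97 + 13))
               % np.uint64(2**31 - 1))


def pda_loglik(params: DDMParams, trials: pd.DataFrame, deadline_s: float,
               config: Optional[PDAConfig] = None, seed: int = 0) -> float:
    """Noisy PDA log-likelihood of one participant-condition's trials.

    ``trials`` must carry stimulus, difficulty, cue, choice, rt_s with
    timeouts already excluded. One fresh synthetic sample is drawn per
    (stimulus cell x cue state) on every call; invariant-violating
    parameters return -inf (auto-reject).
    """
    config = config or PDAConfig()
    if not params.is_valid():
        return -np.inf
    if len(trials) == 0:
        return 0.0
    if (trials["choice"] == "timeout").any():
        raise ValueError("timeouts must be excluded before pda_loglik")
    if params.t_nd >= deadline_s:
        return -np.inf
    max_dec = deadline_s - params.t_nd
    total = 0.0
    k = 0
    for (stim, diff, cue), cell in trials.groupby(
            ["stimulus", "difficulty", "cue"], observed=True, sort=True):
        cue_present = cue == "present"
        if cue_present and params.z_cue is None:
            raise ValueError("cue-present trials require z_cue")
        v = drift_for_stimulus(params, stim, diff)
        z_star = params.z_cue if cue_present else params.z
        obs_rt = cell["rt_s"].to_numpy(dtype=float)
        obs_up = (cell["choice"] == "blast").to_numpy().astype(np.int8)
        total += pda_cell_loglik(
            obs_rt, obs_up, v, params.s_d, params.a, z_star, params.s_z,
            params.s, params.t_nd, config.dt, max_dec, config.n_syn,
            _cell_seed(seed, k), config.floor, config.n_bins)
        k += 1
    return float(total)
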