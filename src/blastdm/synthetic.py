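"""Synthetic experiment generator.

Reproduces the blast-identification task design: six 100-trial main blocks,
two per instruction condition (accuracy: 5 s deadline; speed: 1 s deadline;
bias: probabilistic pre-stimulus cue on half the trials, 65% valid), each
block an equal mix of the four stimulus cells (easy/hard x blast/non-blast).
The block order randomizes one block of each condition and repeats that
order once. Behavior is generated from known ground-truth parameters —
diffusion parameters per condition (choices and RTs) or SDT parameters
(choices only) — so every downstream fit is testable by parameter recovery.

Cue assignment reconciles the equal-cell rule with 65% cue validity by
stratified assignment: exactly half of each bias block's trials are cued and
the cued subset is 65% blast up to rounding (the first bias block rounds
toward the cue, the second rounds down, so the two-block total is exact).
Training and practice trials are not emulated; models are fit to main-task
data only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .ddm import DDMParams, simulate_trials
from .sdt import SDTParams, sdt_rates

CONDITIONS = ("accuracy", "speed", "bias")
STIMULI = ("blast", "nonblast")
DIFFICULTIES = ("easy", "hard")

TRIAL_COLUMNS = ["participant_id", "population", "experience", "block_index",
                 "condition", "cue", "stimulus", "difficulty", "choice",
                 "rt_s", "nomt_accuracy"]

_ENUMS = {
    "population": {"novice", "pathologist"},
    "experience": {"inexperienced", "experienced", ""},
    "condition": set(CONDITIONS),
    "cue": {"none", "present", "absent"},
    "stimulus": set(STIMULI),
    "difficulty": set(DIFFICULTIES),
    "choice": {"blast", "nonblast", "timeout"},
}


@dataclass
class ExperimentConfig:
    n_blocks: int = 6
    trials_per_block: int = 100
    deadline_accuracy_s: float = 5.0
    deadline_speed_s: float = 1.0
    cue_fraction: float = 0.5
    cue_validity: float = 0.65
    fixation_s: float = 0.25      # metadata only; rt_s runs from image onset
    cue_display_s: float = 0.5    # metadata only
    rng_seed: int = 0

    def validate(self) -> None:
        n_cells = len(STIMULI) * len(DIFFICULTIES)
        if self.n_blocks % len(CONDITIONS) != 0:
            raise ValueError("n_blocks must hold equal counts of the three "
                             "instruction conditions")
        if self.trials_per_block % n_cells != 0:
            raise ValueError(
                f"trials_per_block={self.trials_per_block} not divisible by "
                f"{n_cells} stimulus cells")
        if not (0 < self.cue_validity < 1):
            raise ValueError("cue_validity must be in (0, 1)")
        if not (0 < self.cue_fraction <= 1):
            raise ValueError("cue_fraction must be in (0, 1]")
        if self.deadline_accuracy_s <= 0 or self.deadline_speed_s <= 0:
            raise ValueError("deadlines must be positive")

    def deadline(self, condition: str) -> float:
        # bias blocks are untimed relative to speed; they share the 5 s window
        return self.deadline_speed_s if condition == "speed" \
            else self.deadline_accuracy_s


@dataclass
class ParticipantProfile:
    """Ground truth for one simulated participant."""
    participant_id: str
    population: str                       # novice | pathologist
    experience: Optional[str] = None      # inexperienced | experienced
    ddm: Optional[Dict[str, DDMParams]] = None   # per condition
    sdt: Optional[Dict[str, SDTParams]] = None   # per condition
    nomt_accuracy: Optional[float] = None


# ---------------------------------------------------------------------------
# ground-truth group distributions (natural scale, truncated to support)

#: supports used when truncating group distributions on the natural scale;
#: relative start points z/a and z_cue/a live in (0, 1)
_SUPPORT = {
    "s_d": (0.0, np.inf), "a": (1e-4, np.inf), "z_rel": (0.02, 0.98),
    "s_z": (0.0, np.inf), "t_nd": (0.01, np.inf), "z_cue_rel": (0.02, 0.98),
}
_DRIFT_NAMES = ("d_be", "d_bh", "d_nbe", "d_nbh")


@dataclass
class CohortHyper:
    """Natural-scale group locations/scales per condition, for generation.

    per_condition maps condition -> {param name -> (location, scale)} with
    names d_be, d_bh, d_nbe, d_nbh, s_d, a, z_rel, s_z, t_nd (+ z_cue_rel
    in bias). Non-drift parameters are truncated normals on their support.
    """
    population: str
    per_condition: Dict[str, Dict[str, tuple]]


def default_novice_hyper() -> CohortHyper:
    """Documented ground truth for recovery studies (package-chosen values;
    plausible for novice observers: ~70-90% accuracy, sub-second decisions,
    lower threshold under speed pressure, cue shifting the start point up)."""
    drifts = {"d_be": (0.18, 0.04), "d_bh": (0.10, 0.04),
              "d_nbe": (-0.22, 0.04), "d_nbh": (-0.07, 0.04)}
    common = {"s_d": (0.08, 0.02), "z_rel": (0.50, 0.04), "s_z": (0.02, 0.005)}
    return CohortHyper("novice", {
        "accuracy": {**drifts, **common, "a": (0.14, 0.015), "t_nd": (0.35, 0.04)},
        "speed": {**drifts, **common, "a": (0.08, 0.010), "t_nd": (0.30, 0.03)},
        "bias": {**drifts, **common, "a": (0.13, 0.015), "t_nd": (0.35, 0.04),
                 "z_cue_rel": (0.65, 0.04)},
    })


def default_pathologist_hyper() -> CohortHyper:
    """As default_novice_hyper but with the larger drift magnitudes expected
    of trained observers."""
    drifts = {"d_be": (0.32, 0.05), "d_bh": (0.17, 0.04),
              "d_nbe": (-0.36, 0.05), "d_nbh": (-0.13, 0.04)}
    common = {"s_d": (0.08, 0.02), "z_rel": (0.50, 0.04), "s_z": (0.02, 0.005)}
    return CohortHyper("pathologist", {
        "accuracy": {**drifts, **common, "a": (0.14, 0.015), "t_nd": (0.30, 0.03)},
        "speed": {**drifts, **common, "a": (0.08, 0.010), "t_nd": (0.28, 0.03)},
        "bias": {**drifts, **common, "a": (0.13, 0.015), "t_nd": (0.30, 0.03),
                 "z_cue_rel": (0.65, 0.04)},
    })


def default_sdt_hyper() -> Dict[str, Dict[str, Dict[str, tuple]]]:
    """Group (d', c) locations/scales per experience group and condition,
    set to the discriminability ordering novice < inexperienced < experienced
    with mildly liberal criteria."""
    def block(dp, c):
        return {"d_prime": (dp, 0.25), "c": (c, 0.15)}
    return {
        "novice": {"accuracy": block(1.45, -0.07), "speed": block(1.22, -0.05),
                   "bias": block(1.39, -0.12)},
        "inexperienced": {"accuracy": block(2.22, -0.41), "speed": block(1.86, -0.28),
                          "bias": block(2.50, -0.31)},
        "experienced": {"accuracy": block(2.73, -0.16), "speed": block(2.50, -0.11),
                        "bias": block(2.68, -0.13)},
    }


def _draw_truncnorm(loc, scale, lo, hi, rng, n=1):
    if scale == 0:
        return np.full(n, float(np.clip(loc, lo, hi)))
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n,
                               random_state=rng)


def sample_participants(hyper: CohortHyper, n: int, seed: int,
                        experience: Optional[str] = None
                        ) -> List[ParticipantProfile]:
    """Draw n participant profiles from the group distributions.

    Drifts are Normal; constrained parameters are truncated normals on
    their natural support. Joint start-point constraints (z +- s_z/2 inside
    (0, a), same for z_cue) are enforced by redrawing the offending
    participant-condition block. Reproducible given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    for cond, block in hyper.per_condition.items():
        for name, (loc, scale) in block.items():
            if name in _SUPPORT and scale > 0:
                lo, hi = _SUPPORT[name]
                mass = stats.norm.cdf((hi - loc) / scale) - \
                    stats.norm.cdf((lo - loc) / scale)
                if mass < 0.5:
                    import warnings
                    warnings.warn(
                        f"hyper location for {name} ({cond}) puts most mass "
                        "outside the support; draws will be heavily truncated")
    profiles = []
    for i in range(n):
        ddm = {}
        for cond, block in hyper.per_condition.items():
            for _ in range(1000):
                vals = {}
                for name, (loc, scale) in block.items():
                    if name in _DRIFT_NAMES:
                        vals[name] = float(rng.normal(loc, scale))
                    else:
                        lo, hi = _SUPPORT[name]
                        vals[name] = float(
                            _draw_truncnorm(loc, scale, lo, hi, rng)[0])
                p = DDMParams(
                    d_be=vals["d_be"], d_bh=vals["d_bh"],
                    d_nbe=vals["d_nbe"], d_nbh=vals["d_nbh"],
                    s_d=vals["s_d"], a=vals["a"],
                    z=vals["a"] * vals["z_rel"], s_z=vals["s_z"],
                    t_nd=vals["t_nd"],
                    z_cue=vals["a"] * vals["z_cue_rel"]
                    if "z_cue_rel" in vals else None)
                if p.is_valid():
                    ddm[cond] = p
                    break
            else:
                raise RuntimeError("could not draw a valid parameter set; "
                                   "check hyper locations/scales")
        profiles.append(ParticipantProfile(
            participant_id=f"{hyper.population[0]}{i + 1:03d}",
            population=hyper.population, experience=experience, ddm=ddm))
    return profiles


def sample_sdt_participants(group: str, n: int, seed: int,
                            hyper: Optional[dict] = None
                            ) -> List[ParticipantProfile]:
    """Draw profiles with SDT ground truth for one experience group."""
    hyper = (hyper or default_sdt_hyper())[group]
    rng = np.random.default_rng(seed)
    population = "novice" if group == "novice" else "pathologist"
    experience = None if group == "novice" else group
    out = []
    for i in range(n):
        sdt = {}
        for cond, block in hyper.items():
            sdt[cond] = SDTParams(
                d_prime=float(rng.normal(*block["d_prime"])),
                c=float(rng.normal(*block["c"])))
        out.append(ParticipantProfile(
            participant_id=f"{group[0]}{i + 1:03d}", population=population,
            experience=experience, sdt=sdt))
    return out


# ---------------------------------------------------------------------------
# design construction

def _cue_counts(config: ExperimentConfig, bias_block_index: int):
    """(n_cued, n_blast_cued) for the k-th bias block; cumulative-ceiling
    rounding makes the first block round toward the cue and the running
    blast fraction track cue_validity exactly on even block counts."""
    n_cued = int(round(config.trials_per_block * config.cue_fraction))
    prev = math.ceil(config.cue_validity * n_cued * bias_block_index)
    cur = math.ceil(config.cue_validity * n_cued * (bias_block_index + 1))
    return n_cued, cur - prev


def _split_even(total: int, rng) -> tuple:
    """Split total across two strata as evenly as possible, random remainder."""
    lo = total // 2
    if total % 2 == 0:
        return lo, lo
    return (lo + 1, lo) if rng.random() < 0.5 else (lo, lo + 1)


def build_design(config: ExperimentConfig,
                 rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Ordered trial skeletons (no behavior) for one participant.

    Each block holds trials_per_block/4 trials of each stimulus cell,
    shuffled. Block order: one block per condition in random order, the
    sequence then repeated once. Bias blocks carry cue present/absent.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    per_cell = config.trials_per_block // 4
    base_order = list(CONDITIONS)
    rng.shuffle(base_order)
    order = base_order * (config.n_blocks // len(CONDITIONS))
    rows = []
    bias_blocks_seen = 0
    for b, cond in enumerate(order, start=1):
        cells = [(s, d) for s in STIMULI for d in DIFFICULTIES
                 for _ in range(per_cell)]
        if cond != "bias":
            cue = ["none"] * len(cells)
        else:
            n_cued, n_blast_cued = _cue_counts(config, bias_blocks_seen)
            bias_blocks_seen += 1
            n_nonblast_cued = n_cued - n_blast_cued
            cue_flags = {}
            for stim, n_c in (("blast", n_blast_cued),
                              ("nonblast", n_nonblast_cued)):
                if n_c > 2 * per_cell:
                    raise ValueError("cue counts exceed available trials; "
                                     "lower cue_fraction or cue_validity")
                n_easy, n_hard = _split_even(n_c, rng)
                for diff, n_cd in (("easy", n_easy), ("hard", n_hard)):
                    flags = np.zeros(per_cell, dtype=bool)
                    flags[:n_cd] = True
                    rng.shuffle(flags)
                    cue_flags[(stim, diff)] = list(flags)
            cue = ["present" if cue_flags[c].pop() else "absent"
                   for c in cells]
        idx = rng.permutation(len(cells))
        for j in idx:
            rows.append((b, cond, cue[j], cells[j][0], cells[j][1]))
    return pd.DataFrame(rows, columns=["block_index", "condition", "cue",
                                       "stimulus", "difficulty"])


# ---------------------------------------------------------------------------
# behavior simulation

def simulate_dataset(profiles: List[ParticipantProfile],
                     config: ExperimentConfig, model: str = "ddm",
                     seed: int = 0) -> pd.DataFrame:
    """Simulate the full experiment for a cohort; one TrialRecord per trial.

    DDM mode draws (choice, rt) per trial from the diffusion simulator with
    the cue-dependent start point on cued trials; trials whose rt exceeds
    the condition deadline (or that never finish) become timeouts. SDT mode
    draws choices from the hit/false-alarm rates; rt_s is NaN (the model is
    silent about time).
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    if model not in ("ddm", "sdt"):
        raise ValueError("model must be 'ddm' or 'sdt'")
    config.validate()
    rng = np.random.default_rng(seed)
    frames = []
    for prof in profiles:
        design = build_design(config, rng)
        n = len(design)
        choice = np.empty(n, dtype=object)
        rt = np.full(n, np.nan)
        if model == "ddm":
            if prof.ddm is None:
                raise ValueError(f"participant {prof.participant_id}: "
                                 "DDM mode requires ddm parameters")
            for cond in design["condition"].unique():
                if cond not in prof.ddm:
                    raise ValueError(
                        f"participant {prof.participant_id}: missing DDM "
                        f"parameters for condition {cond!r}")
                mask = (design["condition"] == cond).to_numpy()
                sub = design.loc[mask]
                res = simulate_trials(prof.ddm[cond], sub,
                                      seed=int(rng.integers(0, 2**31 - 1)))
                deadline = config.deadline(cond)
                ch = np.where(res.boundary == 1, "blast",
                              np.where(res.boundary == 0, "nonblast",
                                       "timeout"))
                ch = np.where(np.isfinite(res.rt_s) & (res.rt_s > deadline),
                              "timeout", ch)
                choice[mask] = ch
                rt[mask] = np.where(np.isfinite(res.rt_s), res.rt_s, np.nan)
        else:
            if prof.sdt is None:
                raise ValueError(f"participant {prof.participant_id}: "
                                 "SDT mode requires sdt parameters")
            for cond in design["condition"].unique():
                if cond not in prof.sdt:
                    raise ValueError(
                        f"participant {prof.participant_id}: missing SDT "
                        f"parameters for condition {cond!r}")
                mask = (design["condition"] == cond).to_numpy()
                h, f = sdt_rates(prof.sdt[cond])
                stim = design.loc[mask, "stimulus"].to_numpy()
                p_blast = np.where(stim == "blast", h, f)
                u = rng.random(mask.sum())
                choice[mask] = np.where(u < p_blast, "blast", "nonblast")
        out = design.copy()
        out.insert(0, "participant_id", prof.participant_id)
        out.insert(1, "population", prof.population)
        out.insert(2, "experience", prof.experience or "")
        out["choice"] = choice
        out["rt_s"] = rt
        out["nomt_accuracy"] = float(prof.nomt_accuracy) \
            if prof.nomt_accuracy is not None else np.nan
        frames.append(out)
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# trial-table I/O (CSV, UTF-8, "." decimal, lower-case enums)

def write_trials(trials: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table; errors name the offending row."""
    df = pd.read_csv(path, dtype={"participant_id": str},
                     keep_default_na=True)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    if len(df) == 0:
        return df[TRIAL_COLUMNS]
    df["experience"] = df["experience"].fillna("")
    for col, allowed in _ENUMS.items():
        vals = df[col].astype(str)
        bad = ~vals.isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"row {row}: invalid {col} value {df[col].iloc[row]!r} "
                f"(allowed: {sorted(allowed)})")
        df[col] = vals
    rt = df["rt_s"]
    bad = rt.notna() & (rt < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"row {row}: negative rt_s {rt.iloc[row]}")
    bad = (df["condition"] != "bias") ^ (df["cue"] == "none")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"row {row}: cue must be 'none' exactly outside "
                         "bias blocks")
    return df[TRIAL_COLUMNS]
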