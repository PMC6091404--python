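"""Sampling transforms between DDM parameter vectors and natural scale.

The sampler works on an unconstrained vector: drifts are untransformed,
positive parameters (a, s_d, s_z, t_nd) are log-transformed, and start
points are logit-transformed relative to the threshold (z/a, z_cue/a).
The joint constraint z +- s_z/2 inside (0, a) is not encoded by the
transform; it is enforced by the likelihood returning -inf.
"""

from __future__ import annotations

import numpy as np

from .ddm import DDMParams

#: coordinate names on the sampling scale, in vector order
FULL_NAMES = ("d_be", "d_bh", "d_nbe", "d_nbh",
              "log_s_d", "log_a", "logit_z", "log_s_z", "log_t_nd")
BIAS_NAMES = FULL_NAMES + ("logit_z_cue",)
HARD_ONLY_NAMES = ("d_bh", "d_nbh",
                   "log_s_d", "log_a", "logit_z", "log_s_z", "log_t_nd")

#: natural-scale labels matching each sampling coordinate
NATURAL_LABEL = {
    "d_be": "d_be", "d_bh": "d_bh", "d_nbe": "d_nbe", "d_nbh": "d_nbh",
    "log_s_d": "s_d", "log_a": "a", "logit_z": "z_rel",
    "log_s_z": "s_z", "log_t_nd": "t_nd", "logit_z_cue": "z_cue_rel",
}


def param_names(condition: str, hard_only: bool = False):
    """Sampling-coordinate names for one instruction condition."""
    if condition == "bias":
        if hard_only:
            raise ValueError("hard-only fits are used for the accuracy condition")
        return BIAS_NAMES
    if condition in ("speed", "accuracy"):
        return HARD_ONLY_NAMES if hard_only else FULL_NAMES
    raise ValueError(f"unknown condition {condition!r}")


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _logit(p):
    return np.log(p) - np.log1p(-p)


def vector_to_params(vec, names) -> DDMParams:
    """Map a sampling-scale vector to DDMParams (drifts absent from the
    vector, as in hard-trials-only fits, are set to 0 and never used)."""
    d = dict(zip(names, np.asarray(vec, dtype=float)))
    a = float(np.exp(np.clip(d["log_a"], -30, 30)))
    z = a * float(_expit(d["logit_z"]))
    z_cue = a * float(_expit(d["logit_z_cue"])) if "logit_z_cue" in d else None
    return DDMParams(
        d_be=d.get("d_be", 0.0), d_bh=d["d_bh"],
        d_nbe=d.get("d_nbe", 0.0), d_nbh=d["d_nbh"],
        s_d=float(np.exp(np.clip(d["log_s_d"], -30, 30))),
        a=a, z=z,
        s_z=float(np.exp(np.clip(d["log_s_z"], -30, 30))),
        t_nd=float(np.exp(np.clip(d["log_t_nd"], -30, 30))),
        z_cue=z_cue,
    )


def params_to_vector(p: DDMParams, names) -> np.ndarray:
    vals = {
        "d_be": p.d_be, "d_bh": p.d_bh, "d_nbe": p.d_nbe, "d_nbh": p.d_nbh,
        "log_s_d": np.log(p.s_d), "log_a": np.log(p.a),
        "logit_z": _logit(p.z / p.a), "log_s_z": np.log(p.s_z),
        "log_t_nd": np.log(p.t_nd),
    }
    if p.z_cue is not None:
        vals["logit_z_cue"] = _logit(p.z_cue / p.a)
    return np.array([vals[n] for n in names], dtype=float)


def natural_value(name: str, x: float) -> float:
    """Map one sampling coordinate to its natural scale (z as z/a ratio)."""
    if name.startswith("log_"):
        return float(np.exp(x))
    if name.startswith("logit_"):
        return float(_expit(x))
    return float(x)
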