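"""Alternative decision models and the model registry.

Besides the hybrid two-stage race, four comparison models expose the
same trial-level contract (same outcome table schema, ``rpt = rt - gap``
bookkeeping):

* ``independent_race`` — the hybrid race with the interaction removed:
  internal and external variables race independently to the response
  threshold (no transition threshold, no ramp; 5 free parameters).
* ``stanford_simplified`` — a single race between a left and a right
  motor variable; at target onset plus an afferent delay the target-side
  variable accelerates and the distractor-side variable decelerates
  (8 free parameters).
* ``ddm`` — a two-phase drift-diffusion process between bounds ±1000:
  pre-target drift of random sign (the internal decision), post-target
  drift toward the correct bound.
* ``ou`` — the same with a linear leak ``-leak * X`` in the drift;
  ``leak = 0`` reduces exactly to ``ddm``.

Every model entry also provides a common-random-numbers interface
(``sample_base`` / ``solve_rpt``) used by the simulated-likelihood
fitter so the likelihood surface is deterministic and smooth in the
parameters for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from . import hybrid as _hybrid
from .params import RESPONSE_THRESHOLD, DivergedTrialError, HybridParams

__all__ = ["ModelSpec", "MODEL_REGISTRY", "get_model", "simulate_model_trials"]

_HORIZON_MS = 5000.0


def _designs_arrays(designs: pd.DataFrame):
    gap = designs["gap_ms"].to_numpy(dtype=float)
    target = designs["target_side"].to_numpy(dtype="U1")
    if "more_frequent_side" in designs.columns:
        mfs = designs["more_frequent_side"].to_numpy(dtype=object)
    else:
        mfs = np.full(len(designs), None, dtype=object)
    return gap, target, mfs


def _internal_sides(u: np.ndarray, mfs: np.ndarray, alpha: float) -> np.ndarray:
    """Side coded by the internal decision: fair coin, or biased toward
    the cued frequent side with probability ``alpha``."""
    side = np.where(u < 0.5, "L", "R").astype("U1")
    biased = np.array([s in ("L", "R") for s in mfs])
    if biased.any():
        mfs_arr = np.where(biased, mfs, "L").astype("U1")
        other = np.where(mfs_arr == "L", "R", "L").astype("U1")
        side = np.where(biased, np.where(u < alpha, mfs_arr, other), side).astype("U1")
    return side


def _finish(
    gap, target, internal_side, t_int, t_ext, tie_u, exec_delay,
    t_info, on_diverged, horizon_ms=_HORIZON_MS,
) -> pd.DataFrame:
    """Assemble the outcome table shared by the ballistic race models.

    ``t_info`` is the earliest time target information could have
    influenced the eventual winner; responses before it are labelled
    ``internal_only``.
    """
    internal_wins = np.where(t_int == t_ext, tie_u < 0.5, t_int < t_ext)
    t_cross = np.where(internal_wins, t_int, t_ext)
    diverged = ~(t_cross <= horizon_ms)
    if diverged.any():
        if on_diverged == "raise":
            raise DivergedTrialError(
                f"{int(diverged.sum())} trial(s) exceeded the {horizon_ms} ms horizon"
            )
        t_cross = np.where(diverged, np.inf, t_cross)
    rt = t_cross + exec_delay
    response_side = np.where(internal_wins, internal_side, target)
    correct = response_side == target
    congruent = internal_side == target
    congruency = np.where(
        internal_wins & (t_cross < t_info),
        "internal_only",
        np.where(congruent, "congruent", "incongruent"),
    )
    return pd.DataFrame(
        {
            "gap_ms": gap,
            "target_side": target,
            "response_side": response_side,
            "rt_ms": rt,
            "rpt_ms": rt - gap,
            "correct": correct,
            "congruency": congruency,
            "winner": np.where(internal_wins, "internal", "external"),
            "internal_side": internal_side,
        }
    )


# ---------------------------------------------------------------- hybrid

def _hybrid_base(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    return {
        "z_int": rng.standard_normal(n),
        "z_ext": rng.standard_normal(n),
        "u_side": rng.uniform(size=n),
        "tie_u": rng.uniform(size=n),
    }


def _congruent_mask(u: np.ndarray, mfs: np.ndarray, target: np.ndarray,
                    alpha: float) -> np.ndarray:
    """Whether the internal decision codes the target side, without
    materializing side labels (numeric fast path for the likelihood)."""
    biased = np.array([s in ("L", "R") for s in mfs])
    if not biased.any():
        return (u < 0.5) == (target == "L")
    target_is_mfs = target == mfs.astype("U1")
    cong_biased = (u < alpha) == target_is_mfs
    cong_unbiased = (u < 0.5) == (target == "L")
    return np.where(biased, cong_biased, cong_unbiased)


def _hybrid_rpt(params: dict, base: dict, gap, target, mfs):
    """Numeric fast path: rpt and correctness only, divergences censored
    to +inf (they fall outside every observed histogram cell)."""
    theta = params["theta"]
    if not 0.0 < theta < RESPONSE_THRESHOLD:
        # optimizer exploration guard; transforms normally prevent this
        theta = min(max(theta, 1e-6), RESPONSE_THRESHOLD - 1e-6)
    r_int = np.exp(params["mu_int"] + params["sigma_int"] * base["z_int"])
    r_ext = np.exp(params["mu_ext"] + params["sigma_ext"] * base["z_ext"])
    congruent = _congruent_mask(base["u_side"], mfs, target,
                                params.get("alpha", 0.5))
    t_int, t_ext, _ = _hybrid._solve_race(
        r_int, r_ext, congruent, gap, theta, params["A"],
        ramp=params.get("ramp", "linear"),
    )
    internal_wins = np.where(t_int == t_ext, base["tie_u"] < 0.5, t_int < t_ext)
    t_cross = np.where(internal_wins, t_int, t_ext)
    t_cross = np.where(t_cross <= _HORIZON_MS, t_cross, np.inf)
    rpt = t_cross + params["exec_delay"] - gap
    correct = np.where(internal_wins, congruent, True)
    return rpt, correct


def _hybrid_simulate(params: dict, designs, rng, on_diverged="raise"):
    p = HybridParams(
        theta=params["theta"],
        mu_int=params["mu_int"],
        sigma_int=params["sigma_int"],
        mu_ext=params["mu_ext"],
        sigma_ext=params["sigma_ext"],
        exec_delay=params["exec_delay"],
        accel=params["A"],
        alpha=params.get("alpha", 0.5),
    )
    return _hybrid.simulate_trials(p, designs, rng, on_diverged=on_diverged)


# ------------------------------------------------------- independent race

def _indep_base(rng, n):
    return {
        "z_int": rng.standard_normal(n),
        "z_ext": rng.standard_normal(n),
        "u_side": rng.uniform(size=n),
        "tie_u": rng.uniform(size=n),
    }


def _indep_core(params: dict, base: dict, gap, target, mfs, on_diverged):
    r_int = np.exp(params["mu_int"] + params["sigma_int"] * base["z_int"])
    r_ext = np.exp(params["mu_ext"] + params["sigma_ext"] * base["z_ext"])
    side = _internal_sides(base["u_side"], mfs, params.get("alpha", 0.5))
    t_int = RESPONSE_THRESHOLD / r_int
    t_ext = gap + RESPONSE_THRESHOLD / r_ext
    return _finish(
        gap, target, side, t_int, t_ext, base["tie_u"],
        params["exec_delay"], t_info=gap, on_diverged=on_diverged,
    )


def _indep_rpt(params, base, gap, target, mfs):
    r_int = np.exp(params["mu_int"] + params["sigma_int"] * base["z_int"])
    r_ext = np.exp(params["mu_ext"] + params["sigma_ext"] * base["z_ext"])
    congruent = _congruent_mask(base["u_side"], mfs, target,
                                params.get("alpha", 0.5))
    t_int = RESPONSE_THRESHOLD / r_int
    t_ext = gap + RESPONSE_THRESHOLD / r_ext
    internal_wins = np.where(t_int == t_ext, base["tie_u"] < 0.5, t_int < t_ext)
    t_cross = np.where(internal_wins, t_int, t_ext)
    t_cross = np.where(t_cross <= _HORIZON_MS, t_cross, np.inf)
    rpt = t_cross + params["exec_delay"] - gap
    correct = np.where(internal_wins, congruent, True)
    return rpt, correct


def _indep_simulate(params, designs, rng, on_diverged="raise"):
    gap, target, mfs = _designs_arrays(designs)
    return _indep_core(params, _indep_base(rng, len(gap)), gap, target, mfs,
                       on_diverged)


# ---------------------------------------------------- Stanford-style race

def _stanford_base(rng, n):
    return {
        "z1": rng.standard_normal(n),
        "z2": rng.standard_normal(n),
        "tie_u": rng.uniform(size=n),
    }


def _stanford_core(params: dict, base: dict, gap, target, mfs, on_diverged):
    rho = params["rate_corr"]
    z_t = base["z1"]
    z_d = rho * base["z1"] + np.sqrt(max(1.0 - rho**2, 0.0)) * base["z2"]
    # z1/z2 are exchangeable, so assigning z1 to the target-side variable
    # does not break the pre-target symmetry between left and right
    r_t = np.exp(params["mu_build"] + params["sigma_build"] * z_t)
    r_d = np.exp(params["mu_build"] + params["sigma_build"] * z_d)
    t_c = gap + params["afferent_delay"]

    def crossing(r, dr):
        t_free = RESPONSE_THRESHOLD / r
        need = RESPONSE_THRESHOLD - r * t_c
        s = _hybrid._ramp_crossing_linear(need, r, dr, params["ramp_ms"])
        return np.where(t_free <= t_c, t_free, t_c + s)

    t_target = crossing(r_t, params["accel"])
    t_distr = crossing(r_d, -params["decel"])
    # leader at information arrival = the variable with the larger rate
    leader_is_target = np.where(r_t == r_d, base["tie_u"] < 0.5, r_t > r_d)
    distractor = np.where(target == "L", "R", "L").astype("U1")
    internal_side = np.where(leader_is_target, target, distractor).astype("U1")
    # map onto the shared bookkeeping: "internal" = the leading variable
    t_int = np.where(leader_is_target, t_target, t_distr)
    t_ext = np.where(leader_is_target, t_distr, t_target)
    out = _finish(
        gap, target, internal_side, t_int, t_ext, base["tie_u"],
        params["exec_delay"], t_info=t_c, on_diverged=on_diverged,
    )
    # the non-leading variable codes its own side, not necessarily the target
    ext_side = np.where(leader_is_target, distractor, target).astype("U1")
    ext_wins = out["winner"].to_numpy() == "external"
    out["response_side"] = np.where(ext_wins, ext_side, internal_side)
    out["correct"] = out["response_side"].to_numpy() == target
    return out


def _stanford_rpt(params, base, gap, target, mfs):
    out = _stanford_core(params, base, gap, target, mfs, on_diverged="censor")
    return out["rpt_ms"].to_numpy(), out["correct"].to_numpy()


def _stanford_simulate(params, designs, rng, on_diverged="raise"):
    gap, target, mfs = _designs_arrays(designs)
    return _stanford_core(params, _stanford_base(rng, len(gap)), gap, target,
                          mfs, on_diverged)


# ------------------------------------------------------- diffusion models

_DT_MS = 1.0


def _diffusion_base(rng, n, horizon_ms=_HORIZON_MS):
    # noise increments are drawn lazily per step in _diffusion_core with a
    # child generator so memory stays bounded; the base stores its seed
    return {
        "u_side": rng.uniform(size=n),
        "noise_seed": int(rng.integers(0, 2**31 - 1)),
    }


def _diffusion_core(params: dict, base: dict, gap, target, mfs, on_diverged,
                    leak: float = 0.0):
    n = len(gap)
    bound = RESPONSE_THRESHOLD
    side = _internal_sides(base["u_side"], mfs, params.get("alpha", 0.5))
    sign_int = np.where(side == target, 1.0, -1.0)  # target-coordinate drift sign
    s = params["noise"]
    v_int = params["v_int"]
    v_ext = params["v_ext"]
    noise_rng = np.random.default_rng(base["noise_seed"])

    x = np.zeros(n)
    t_cross = np.full(n, np.inf)
    hit_upper = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    n_steps = int(_HORIZON_MS / _DT_MS)
    sqrt_dt = np.sqrt(_DT_MS)
    for step in range(n_steps):
        t = step * _DT_MS
        if not active.any():
            break
        idx = np.flatnonzero(active)
        drift = np.where(t >= gap[idx], v_ext, sign_int[idx] * v_int)
        if leak:
            drift = drift - leak * x[idx]
        x[idx] += drift * _DT_MS + s * sqrt_dt * noise_rng.standard_normal(len(idx))
        crossed = np.abs(x[idx]) >= bound
        if crossed.any():
            j = idx[crossed]
            t_cross[j] = t + _DT_MS
            hit_upper[j] = x[j] >= bound
            active[j] = False
    if active.any():
        if on_diverged == "raise":
            raise DivergedTrialError(
                f"{int(active.sum())} trial(s) exceeded the {_HORIZON_MS} ms horizon"
            )
    rt = t_cross + params["exec_delay"]
    distractor = np.where(target == "L", "R", "L").astype("U1")
    response_side = np.where(hit_upper, target, distractor).astype("U1")
    correct = response_side == target
    congruent = side == target
    congruency = np.where(
        t_cross < gap,
        "internal_only",
        np.where(congruent, "congruent", "incongruent"),
    )
    winner = np.where(t_cross < gap, "internal", "external")
    return pd.DataFrame(
        {
            "gap_ms": gap,
            "target_side": target,
            "response_side": response_side,
            "rt_ms": rt,
            "rpt_ms": rt - gap,
            "correct": correct,
            "congruency": congruency,
            "winner": winner,
            "internal_side": side,
        }
    )


def _ddm_rpt(params, base, gap, target, mfs):
    out = _diffusion_core(params, base, gap, target, mfs, on_diverged="censor")
    return out["rpt_ms"].to_numpy(), out["correct"].to_numpy()


def _ddm_simulate(params, designs, rng, on_diverged="raise"):
    gap, target, mfs = _designs_arrays(designs)
    return _diffusion_core(params, _diffusion_base(rng, len(gap)), gap, target,
                           mfs, on_diverged)


def _ou_rpt(params, base, gap, target, mfs):
    out = _diffusion_core(params, base, gap, target, mfs, on_diverged="censor",
                          leak=params["leak"])
    return out["rpt_ms"].to_numpy(), out["correct"].to_numpy()


def _ou_simulate(params, designs, rng, on_diverged="raise"):
    gap, target, mfs = _designs_arrays(designs)
    return _diffusion_core(params, _diffusion_base(rng, len(gap)), gap, target,
                           mfs, on_diverged, leak=params["leak"])


# ---------------------------------------------------------------- registry

@dataclass(frozen=True)
class ModelSpec:
    """Registry entry for one decision model.

    ``transforms`` maps each parameter to the reparameterization used by
    the fitter (``identity``, ``log``, ``logit_threshold`` for the
    transition threshold scaled by the response threshold, ``logit`` for
    probabilities, ``atanh`` for correlations).  ``start_ranges`` are
    natural-scale ranges from which multi-start initial points are
    drawn.
    """

    name: str
    param_names: tuple[str, ...]
    transforms: dict[str, str]
    start_ranges: dict[str, tuple[float, float]]
    defaults: dict[str, float]
    simulate: Callable[..., pd.DataFrame]
    sample_base: Callable[[np.random.Generator, int], dict]
    solve_rpt: Callable[..., tuple[np.ndarray, np.ndarray]]
    bias_param: str | None = None

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def param_names_with_bias(self, bias: bool) -> tuple[str, ...]:
        if bias and self.bias_param is not None:
            return self.param_names + (self.bias_param,)
        return self.param_names


MODEL_REGISTRY: dict[str, ModelSpec] = {
    "hybrid": ModelSpec(
        name="hybrid",
        param_names=("theta", "mu_int", "sigma_int", "mu_ext", "sigma_ext",
                     "exec_delay", "A"),
        transforms={
            "theta": "logit_threshold", "mu_int": "identity",
            "sigma_int": "log", "mu_ext": "identity", "sigma_ext": "log",
            "exec_delay": "log", "A": "log", "alpha": "logit",
        },
        start_ranges={
            "theta": (250, 750), "mu_int": (0.5, 2.2), "sigma_int": (0.4, 1.8),
            "mu_ext": (0.3, 2.0), "sigma_ext": (0.2, 0.9),
            "exec_delay": (80, 180), "A": (5, 110), "alpha": (0.52, 0.75),
        },
        defaults={"theta": 500, "mu_int": 1.4, "sigma_int": 1.2,
                  "mu_ext": 1.1, "sigma_ext": 0.4, "exec_delay": 125,
                  "A": 40, "alpha": 0.5},
        simulate=_hybrid_simulate,
        sample_base=_hybrid_base,
        solve_rpt=_hybrid_rpt,
        bias_param="alpha",
    ),
    "independent_race": ModelSpec(
        name="independent_race",
        param_names=("mu_int", "sigma_int", "mu_ext", "sigma_ext", "exec_delay"),
        transforms={"mu_int": "identity", "sigma_int": "log",
                    "mu_ext": "identity", "sigma_ext": "log",
                    "exec_delay": "log", "alpha": "logit"},
        start_ranges={"mu_int": (0.5, 2.2), "sigma_int": (0.4, 1.8),
                      "mu_ext": (0.3, 2.0), "sigma_ext": (0.2, 0.9),
                      "exec_delay": (80, 180), "alpha": (0.52, 0.75)},
        defaults={"mu_int": 1.4, "sigma_int": 1.2, "mu_ext": 1.1,
                  "sigma_ext": 0.4, "exec_delay": 125, "alpha": 0.5},
        simulate=_indep_simulate,
        sample_base=_indep_base,
        solve_rpt=_indep_rpt,
        bias_param="alpha",
    ),
    "stanford_simplified": ModelSpec(
        name="stanford_simplified",
        param_names=("mu_build", "sigma_build", "accel", "decel",
                     "afferent_delay", "exec_delay", "ramp_ms", "rate_corr"),
        transforms={"mu_build": "identity", "sigma_build": "log",
                    "accel": "log", "decel": "log", "afferent_delay": "log",
                    "exec_delay": "log", "ramp_ms": "log", "rate_corr": "atanh"},
        start_ranges={"mu_build": (0.5, 2.0), "sigma_build": (0.3, 1.5),
                      "accel": (1.0, 8.0), "decel": (1.0, 8.0),
                      "afferent_delay": (20, 120), "exec_delay": (80, 180),
                      "ramp_ms": (5, 100), "rate_corr": (-0.3, 0.8)},
        defaults={"mu_build": 1.3, "sigma_build": 0.8, "accel": 3.0,
                  "decel": 3.0, "afferent_delay": 60, "exec_delay": 125,
                  "ramp_ms": 30, "rate_corr": 0.3},
        simulate=_stanford_simulate,
        sample_base=_stanford_base,
        solve_rpt=_stanford_rpt,
    ),
    "ddm": ModelSpec(
        name="ddm",
        param_names=("v_int", "v_ext", "noise", "exec_delay"),
        transforms={"v_int": "log", "v_ext": "log", "noise": "log",
                    "exec_delay": "log", "alpha": "logit"},
        start_ranges={"v_int": (1.0, 6.0), "v_ext": (1.0, 8.0),
                      "noise": (10.0, 80.0), "exec_delay": (80, 180),
                      "alpha": (0.52, 0.75)},
        defaults={"v_int": 3.0, "v_ext": 4.0, "noise": 40.0,
                  "exec_delay": 125, "alpha": 0.5},
        simulate=_ddm_simulate,
        sample_base=_diffusion_base,
        solve_rpt=_ddm_rpt,
        bias_param="alpha",
    ),
    "ou": ModelSpec(
        name="ou",
        param_names=("v_int", "v_ext", "noise", "exec_delay", "leak"),
        transforms={"v_int": "log", "v_ext": "log", "noise": "log",
                    "exec_delay": "log", "leak": "log", "alpha": "logit"},
        start_ranges={"v_int": (1.0, 6.0), "v_ext": (1.0, 8.0),
                      "noise": (10.0, 80.0), "exec_delay": (80, 180),
                      "leak": (1e-4, 5e-3), "alpha": (0.52, 0.75)},
        defaults={"v_int": 3.0, "v_ext": 4.0, "noise": 40.0,
                  "exec_delay": 125, "leak": 1e-3, "alpha": 0.5},
        simulate=_ou_simulate,
        sample_base=_diffusion_base,
        solve_rpt=_ou_rpt,
        bias_param="alpha",
    ),
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered models: "
            f"{sorted(MODEL_REGISTRY)}"
        ) from None


def simulate_model_trials(
    name: str,
    params: dict,
    designs: pd.DataFrame,
    rng: np.random.Generator,
    on_diverged: str = "raise",
) -> pd.DataFrame:
    """Simulate any registered model over a design table."""
    return get_model(name).simulate(params, designs, rng, on_diverged=on_diverged)
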