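"""Simulation of the hybrid two-stage race model.

Trajectories are deterministic given the sampled rates (no within-trial
diffusion noise and no afferent delay on the external variable), so every
event time has a closed piecewise linear/quadratic form and whole trial
batches are solved vectorially.

Timeline of one trial (all times in ms, t = 0 at the action-initiating
key press):

* internal variable ``X_I(t) = r_I * t`` from t = 0;
* external variable ``X_E(t) = r_E * (t - gap)`` from t = gap;
* the interaction (stage 2) starts at ``t_trans``, the first time both
  variables exceed the transition threshold ``theta``;
* from ``t_trans`` the internal slope moves from ``r_I`` to
  ``r_I + r_E`` (congruent) or ``r_I - r_E`` (incongruent).  With the
  default linear ramp the transition completes in exactly ``A`` ms; with
  the exponential form it relaxes with time constant ``A``.  The
  external slope is never modified;
* the first variable to reach the response threshold (1000) determines
  the response side; its crossing time plus the execution delay is the
  response time.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .params import (
    RESPONSE_THRESHOLD,
    DivergedTrialError,
    HybridParams,
    RaceInputs,
    TrialDesign,
    TrialOutcome,
)

__all__ = [
    "sample_trial_inputs",
    "solve_hybrid_race",
    "simulate_trial",
    "simulate_trials",
    "simulate_experiment",
]

def _other(side: str) -> str:
    return "R" if side == "L" else "L"


def sample_trial_inputs(
    params: HybridParams, design: TrialDesign, rng: np.random.Generator
) -> RaceInputs:
    """Draw the latent inputs of one trial.

    Rates are lognormal, ``r = exp(mu + sigma * z)`` with standard-normal
    ``z``.  The internal variable's side is a fair coin flip, except in
    the biased design where it equals ``more_frequent_side`` with
    probability ``alpha``.
    """
    r_int = float(np.exp(params.mu_int + params.sigma_int * rng.standard_normal()))
    r_ext = float(np.exp(params.mu_ext + params.sigma_ext * rng.standard_normal()))
    u = rng.uniform()
    if design.more_frequent_side is None:
        internal_side = "L" if u < 0.5 else "R"
    else:
        internal_side = (
            design.more_frequent_side
            if u < params.alpha
            else _other(design.more_frequent_side)
        )
    return RaceInputs(r_int=r_int, r_ext=r_ext, internal_side=internal_side)


def _ramp_crossing_linear(
    need: np.ndarray, r_i: np.ndarray, dr: np.ndarray, accel: float | np.ndarray
) -> np.ndarray:
    """Time (from ramp start) at which a ramped accumulator gains ``need``.

    The slope interpolates linearly from ``r_i`` to ``r_i + dr`` over
    ``accel`` ms and stays at ``r_i + dr`` afterwards.  Returns +inf for
    trials whose accumulator never gains ``need`` (possible only when
    ``r_i + dr <= 0``).  All arguments broadcast.
    """
    need = np.asarray(need, dtype=float)
    r_i = np.asarray(r_i, dtype=float)
    dr = np.asarray(dr, dtype=float)
    accel = np.asarray(accel, dtype=float)

    a = dr / (2.0 * accel)  # quadratic coefficient during the ramp
    disc = r_i**2 + 4.0 * a * need
    with np.errstate(invalid="ignore", divide="ignore"):
        sqrt_disc = np.sqrt(np.maximum(disc, 0.0))
        # smallest positive root of a*s^2 + r_i*s - need = 0 (both signs of a)
        s_ramp = np.where(a != 0.0, (-r_i + sqrt_disc) / (2.0 * a), need / r_i)
    gain_full_ramp = (r_i + 0.5 * dr) * accel
    crossed_in_ramp = (disc >= 0.0) & (s_ramp >= 0.0) & (s_ramp <= accel)

    r_final = r_i + dr
    with np.errstate(invalid="ignore", divide="ignore"):
        s_after = accel + (need - gain_full_ramp) / r_final
    s_after = np.where(r_final > 0.0, s_after, np.inf)
    return np.where(crossed_in_ramp, s_ramp, s_after)


def _ramp_crossing_exponential(
    need: np.ndarray, r_i: np.ndarray, dr: np.ndarray, accel: float
) -> np.ndarray:
    """Like :func:`_ramp_crossing_linear` but the slope relaxes
    exponentially toward ``r_i + dr`` with time constant ``accel``:
    ``X(s) - X(0) = r_f s + (r_i - r_f) * accel * (1 - exp(-s/accel))``.

    Solved by vectorized bisection (the gain is not algebraic).
    """
    need = np.asarray(need, dtype=float)
    r_i, dr = np.broadcast_arrays(
        np.asarray(r_i, dtype=float), np.asarray(dr, dtype=float)
    )
    r_f = r_i + dr

    def gain(s: np.ndarray) -> np.ndarray:
        return r_f * s + (r_i - r_f) * accel * (1.0 - np.exp(-s / accel))

    # peak gain for decaying slopes: slope zero at s* = accel*ln((r_i-r_f)/(-r_f))
    with np.errstate(invalid="ignore", divide="ignore"):
        s_peak = accel * np.log((r_i - r_f) / np.where(r_f < 0, -r_f, np.nan))
    reachable = np.where(r_f < 0, gain(np.where(r_f < 0, s_peak, 0.0)) >= need, True)

    hi = np.where(r_f < 0, np.where(reachable, s_peak, 1.0), accel)
    # expand hi until gain(hi) >= need where the target is reachable
    for _ in range(200):
        short = reachable & (gain(hi) < need)
        if not short.any():
            break
        hi = np.where(short, hi * 2.0, hi)
    lo = np.zeros_like(hi)
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        below = gain(mid) < need
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return np.where(reachable, 0.5 * (lo + hi), np.inf)


def _solve_race(
    r_int: np.ndarray,
    r_ext: np.ndarray,
    congruent: np.ndarray,
    gap: np.ndarray,
    theta: float,
    accel: float,
    ramp: str = "linear",
    response_threshold: float = RESPONSE_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized event times of the hybrid race.

    Returns ``(t_int_cross, t_ext_cross, t_ext_theta)``: the response
    threshold crossing time of each variable (+inf when never) and the
    external variable's transition-threshold crossing time.
    """
    t_int_theta = theta / r_int
    t_ext_theta = gap + theta / r_ext
    t_trans = np.maximum(t_int_theta, t_ext_theta)
    t_ext_cross = gap + response_threshold / r_ext
    t_int_free = response_threshold / r_int

    # Internal variable still below the response threshold when stage 2 starts?
    staged = t_int_free > t_trans
    need = response_threshold - r_int * t_trans
    dr = np.where(congruent, r_ext, -r_ext)
    if ramp == "linear":
        s = _ramp_crossing_linear(need, r_int, dr, accel)
    elif ramp == "exponential":
        s = _ramp_crossing_exponential(need, r_int, dr, accel)
    else:
        raise ValueError(f"unknown ramp form: {ramp!r}")
    t_int_cross = np.where(staged, t_trans + s, t_int_free)
    return t_int_cross, t_ext_cross, t_ext_theta


def _solve_outcomes(
    r_int: np.ndarray,
    r_ext: np.ndarray,
    internal_side: np.ndarray,
    gap: np.ndarray,
    target_side: np.ndarray,
    params: HybridParams,
    tie_u: np.ndarray,
    ramp: str = "linear",
    horizon_ms: float = 5000.0,
    on_diverged: str = "raise",
) -> pd.DataFrame:
    """Solve a batch of trials given pre-sampled latent inputs."""
    congruent = internal_side == target_side
    t_int, t_ext, t_ext_theta = _solve_race(
        r_int,
        r_ext,
        congruent,
        gap,
        params.theta,
        params.accel,
        ramp=ramp,
        response_threshold=params.response_threshold,
    )
    # tie resolution: measure-zero under continuous rates, but must stay
    # deterministic under the trial's rng
    internal_wins = np.where(t_int == t_ext, tie_u < 0.5, t_int < t_ext)
    t_cross = np.where(internal_wins, t_int, t_ext)

    diverged = ~(t_cross <= horizon_ms)
    if diverged.any():
        if on_diverged == "raise":
            raise DivergedTrialError(
                f"{int(diverged.sum())} trial(s) exceeded the {horizon_ms} ms horizon"
            )
        if on_diverged != "censor":
            raise ValueError("on_diverged must be 'raise' or 'censor'")
        t_cross = np.where(diverged, np.inf, t_cross)

    rt = t_cross + params.exec_delay
    response_side = np.where(internal_wins, internal_side, target_side)
    correct = response_side == target_side
    internal_only = internal_wins & (t_cross < t_ext_theta)
    congruency = np.where(
        internal_only,
        "internal_only",
        np.where(congruent, "congruent", "incongruent"),
    )
    return pd.DataFrame(
        {
            "gap_ms": gap,
            "target_side": target_side,
            "response_side": response_side,
            "rt_ms": rt,
            "rpt_ms": rt - gap,
            "correct": correct,
            "congruency": congruency,
            "winner": np.where(internal_wins, "internal", "external"),
            "internal_side": internal_side,
            "r_int": r_int,
            "r_ext": r_ext,
        }
    )


def solve_hybrid_race(
    inputs: RaceInputs,
    design: TrialDesign,
    params: HybridParams,
    ramp: str = "linear",
    horizon_ms: float = 5000.0,
    tie_rng: np.random.Generator | None = None,
) -> TrialOutcome:
    """Deterministically resolve one trial from its latent inputs."""
    tie_u = tie_rng.uniform() if tie_rng is not None else 0.0
    df = _solve_outcomes(
        np.array([inputs.r_int]),
        np.array([inputs.r_ext]),
        np.array([inputs.internal_side]),
        np.array([float(design.gap_ms)]),
        np.array([design.target_side]),
        params,
        np.array([tie_u]),
        ramp=ramp,
        horizon_ms=horizon_ms,
    )
    row = df.iloc[0]
    return TrialOutcome(
        response_side=row["response_side"],
        rt_ms=float(row["rt_ms"]),
        rpt_ms=float(row["rpt_ms"]),
        correct=bool(row["correct"]),
        congruency=row["congruency"],
        winner=row["winner"],
        internal_side=row["internal_side"],
    )


def simulate_trial(
    params: HybridParams,
    design: TrialDesign,
    rng: np.random.Generator,
    ramp: str = "linear",
    horizon_ms: float = 5000.0,
) -> TrialOutcome:
    """Sample latent inputs and resolve one stochastic trial."""
    inputs = sample_trial_inputs(params, design, rng)
    return solve_hybrid_race(
        inputs, design, params, ramp=ramp, horizon_ms=horizon_ms, tie_rng=rng
    )


def simulate_trials(
    params: HybridParams,
    designs: pd.DataFrame,
    rng: np.random.Generator,
    ramp: str = "linear",
    horizon_ms: float = 5000.0,
    on_diverged: str = "raise",
) -> pd.DataFrame:
    """Simulate a batch of trials (vectorized).

    Parameters
    ----------
    designs : DataFrame
        Columns ``gap_ms``, ``target_side`` and optionally
        ``more_frequent_side`` (NaN/None = unbiased trial).

    Returns
    -------
    DataFrame with one row per design row: the design columns plus
    ``response_side, rt_ms, rpt_ms, correct, congruency, winner`` and the
    latent columns ``internal_side, r_int, r_ext`` (simulation-only).
    """
    n = len(designs)
    if n == 0:
        raise ValueError("designs must contain at least one trial")
    gap = designs["gap_ms"].to_numpy(dtype=float)
    target = designs["target_side"].to_numpy(dtype="U1")

    z_int = rng.standard_normal(n)
    z_ext = rng.standard_normal(n)
    u_side = rng.uniform(size=n)
    tie_u = rng.uniform(size=n)
    r_int = np.exp(params.mu_int + params.sigma_int * z_int)
    r_ext = np.exp(params.mu_ext + params.sigma_ext * z_ext)

    if "more_frequent_side" in designs.columns:
        mfs = designs["more_frequent_side"].to_numpy(dtype=object)
    else:
        mfs = np.full(n, None, dtype=object)
    biased = np.array([s in ("L", "R") for s in mfs])
    internal_side = np.where(u_side < 0.5, "L", "R").astype("U1")
    if biased.any():
        mfs_arr = np.where(biased, mfs, "L").astype("U1")
        other = np.where(mfs_arr == "L", "R", "L").astype("U1")
        chosen = np.where(u_side < params.alpha, mfs_arr, other)
        internal_side = np.where(biased, chosen, internal_side).astype("U1")

    out = _solve_outcomes(
        r_int,
        r_ext,
        internal_side,
        gap,
        target,
        params,
        tie_u,
        ramp=ramp,
        horizon_ms=horizon_ms,
        on_diverged=on_diverged,
    )
    if "more_frequent_side" in designs.columns:
        out.insert(1, "more_frequent_side", mfs)
    if "trial_id" in designs.columns:
        out.insert(0, "trial_id", designs["trial_id"].to_numpy())
    else:
        out.insert(0, "trial_id", np.arange(n))
    return out


def simulate_experiment(
    params_per_subject: Sequence[HybridParams],
    designs_per_subject: Iterable[pd.DataFrame],
    rng: np.random.Generator,
    ramp: str = "linear",
    horizon_ms: float = 5000.0,
    on_diverged: str = "raise",
) -> pd.DataFrame:
    """Simulate several subjects and stack them into one tidy trial table.

    Latent columns (``internal_side``, ``r_int``, ``r_ext``,
    ``congruency``, ``winner``) are present and flagged simulation-only
    in the schema; :mod:`dualrace.synthetic` splits them into a sidecar.
    """
    params_per_subject = list(params_per_subject)
    if not params_per_subject:
        raise ValueError("need at least one subject")
    frames = []
    for subject, (params, designs) in enumerate(
        zip(params_per_subject, designs_per_subject, strict=True), start=1
    ):
        df = simulate_trials(
            params, designs, rng, ramp=ramp, horizon_ms=horizon_ms,
            on_diverged=on_diverged,
        )
        df.insert(0, "subject", subject)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
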