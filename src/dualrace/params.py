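"""Core domain types for the two-stage (hybrid) race model.

The hybrid model describes choice behavior in the gap paradigm: a
participant commits to initiating a left/right response before the
discriminative stimulus appears (the *gap* separates the action-initiating
key press from target onset).  Two evidence variables race to a common
response threshold: an *internal* variable coding a self-generated choice,
accumulating from the key press, and an *external* variable coding the
stimulus-defined correct side, accumulating from target onset.  Once both
variables exceed a *transition threshold* the external variable starts to
drive the internal one (facilitation when they code the same side,
inhibition otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "RESPONSE_THRESHOLD",
    "HybridParams",
    "TrialDesign",
    "RaceInputs",
    "TrialOutcome",
    "DivergedTrialError",
]

#: Common response threshold (evidence units).  Fixed by convention; all
#: rate and threshold parameters are scaled relative to it.
RESPONSE_THRESHOLD: float = 1000.0


class DivergedTrialError(RuntimeError):
    """No accumulator reached the response threshold within the horizon."""


@dataclass(frozen=True)
class HybridParams:
    """Free parameters of the hybrid two-stage race model.

    Parameters
    ----------
    theta : float
        Transition threshold (evidence units), ``0 < theta < 1000``.
        Both variables must exceed it before they interact.
    mu_int, sigma_int : float
        Natural-log location and scale of the lognormal distribution of
        the internal accumulation rate (evidence units / ms).
    mu_ext, sigma_ext : float
        Same for the external accumulation rate.
    exec_delay : float
        Non-decision execution delay added to the threshold-crossing
        time (ms).
    accel : float
        Interaction time constant ``A`` (ms): the time the external
        variable needs to fully add to (congruent) or subtract from
        (incongruent) the internal rate.
    alpha : float
        Probability that the internal variable codes the cued
        more-frequent side (0.5 = unbiased, the default).
    """

    theta: float
    mu_int: float
    sigma_int: float
    mu_ext: float
    sigma_ext: float
    exec_delay: float
    accel: float
    alpha: float = 0.5
    response_threshold: float = field(default=RESPONSE_THRESHOLD)

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < self.response_threshold:
            raise ValueError(
                f"theta must lie in (0, {self.response_threshold}); got {self.theta}"
            )
        if self.sigma_int <= 0 or self.sigma_ext <= 0:
            raise ValueError("sigma_int and sigma_ext must be positive")
        if self.exec_delay < 0:
            raise ValueError("exec_delay must be >= 0")
        if self.accel <= 0:
            raise ValueError("accel (A) must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def with_alpha(self, alpha: float) -> "HybridParams":
        return replace(self, alpha=alpha)


@dataclass(frozen=True)
class TrialDesign:
    """Experimental inputs of one trial.

    ``gap_ms`` is the delay between the action-initiating key press
    (t = 0) and target onset.  ``more_frequent_side`` is the
    cue-conditional frequent target side in the biased experiment
    (``None`` when the design is unbiased).
    """

    gap_ms: float
    target_side: str
    more_frequent_side: str | None = None
    trial_id: int = 0

    def __post_init__(self) -> None:
        if self.gap_ms < 0:
            raise ValueError("gap_ms must be >= 0")
        if self.target_side not in ("L", "R"):
            raise ValueError("target_side must be 'L' or 'R'")
        if self.more_frequent_side not in (None, "L", "R"):
            raise ValueError("more_frequent_side must be 'L', 'R' or None")


@dataclass(frozen=True)
class RaceInputs:
    """Latent per-trial inputs of the race: sampled rates and the side
    coded by the internal variable."""

    r_int: float
    r_ext: float
    internal_side: str

    def __post_init__(self) -> None:
        if self.r_int <= 0 or self.r_ext <= 0:
            raise ValueError("accumulation rates must be positive")
        if self.internal_side not in ("L", "R"):
            raise ValueError("internal_side must be 'L' or 'R'")


@dataclass(frozen=True)
class TrialOutcome:
    """One simulated (or observed) trial response.

    ``rpt_ms`` (raw processing time) is ``rt_ms - gap_ms``: the time
    target information was available before the choice response
    (negative when the response preceded target onset).  ``congruency``
    is ``internal_only`` when the response occurred before the external
    variable had crossed the transition threshold, i.e. before target
    information could have influenced the choice.
    """

    response_side: str
    rt_ms: float
    rpt_ms: float
    correct: bool
    congruency: str
    winner: str
    internal_side: str | None = None

    def __post_init__(self) -> None:
        if self.congruency not in ("congruent", "incongruent", "internal_only"):
            raise ValueError(f"invalid congruency label: {self.congruency}")
        if self.winner not in ("internal", "external"):
            raise ValueError(f"invalid winner label: {self.winner}")
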