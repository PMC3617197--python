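"""Synthetic gap-paradigm experiments.

Generates trial designs and full model-generated datasets emulating the
studies' paradigm: gaps uniform on 0–330 ms measured from the
action-initiating key press; target side 50/50 (unbiased design) or
65/35 conditional on a balanced auditory cue, with the cue-to-side
assignment counterbalanced across subject halves.  The 850 ms response
deadline and 20-trial feedback blocks of the original task are recorded
as metadata only — the model has no feedback-adaptation mechanism, so
they do not alter generation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .hybrid import simulate_trials
from .reference_params import params_from_row

__all__ = ["ExperimentConfig", "generate_designs", "generate_dataset",
           "PUBLIC_COLUMNS", "LATENT_COLUMNS"]

#: Columns of the public trial table (what an experimenter observes).
PUBLIC_COLUMNS = [
    "subject", "trial_id", "gap_ms", "rt_ms", "response_side",
    "target_side", "correct", "more_frequent_side",
]
#: Simulation-only columns, emitted in the ground-truth sidecar.
LATENT_COLUMNS = ["subject", "trial_id", "internal_side", "congruency",
                  "winner", "r_int", "r_ext"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Design configuration for one synthetic experiment."""

    n_subjects: int = 10
    n_trials_per_subject: int = 540
    gap_range_ms: tuple[float, float] = (0.0, 330.0)
    bias: float | None = None  # None = unbiased; 0.65 = cued design
    rt_deadline_ms: float = 850.0  # metadata only
    feedback_block: int = 20  # metadata only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_subject < 1:
            raise ValueError("need at least one subject and one trial")
        if self.gap_range_ms[0] < 0 or self.gap_range_ms[1] <= self.gap_range_ms[0]:
            raise ValueError("invalid gap range")
        if self.bias is not None and not 0.5 < self.bias < 1.0:
            raise ValueError("bias must lie in (0.5, 1) when set")


def generate_designs(
    config: ExperimentConfig,
    rng: np.random.Generator,
    subject: int = 1,
) -> pd.DataFrame:
    """Trial designs for one subject.

    Unbiased design: target side is a fair coin.  Biased design: a
    balanced binary cue precedes each trial; the cued side is the target
    with probability ``bias``.  Which cue maps to which side alternates
    between subject halves (odd subjects: cue 0 -> right more frequent).
    """
    n = config.n_trials_per_subject
    gaps = rng.uniform(*config.gap_range_ms, size=n)
    if config.bias is None:
        target = np.where(rng.uniform(size=n) < 0.5, "L", "R")
        mfs = np.full(n, None, dtype=object)
    else:
        cue = rng.integers(0, 2, size=n)
        group_flip = subject % 2 == 0
        mfs = np.where(cue == 0, "R", "L")
        if group_flip:
            mfs = np.where(cue == 0, "L", "R")
        other = np.where(mfs == "L", "R", "L")
        target = np.where(rng.uniform(size=n) < config.bias, mfs, other)
        mfs = mfs.astype(object)
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "gap_ms": gaps,
            "target_side": target.astype("U1"),
            "more_frequent_side": mfs,
        }
    )


def generate_dataset(
    param_table: pd.DataFrame,
    config: ExperimentConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full synthetic dataset: public trial table plus ground-truth sidecar.

    ``param_table`` must hold one row per subject in the layout of
    :mod:`dualrace.reference_params` (an ``alpha`` column makes the
    model's internal choice biased).  Returns ``(trials, truth)``;
    ``truth`` carries the latent columns and the generating parameters,
    joining ``trials`` exactly on (subject, trial_id).
    """
    if len(param_table) == 0:
        raise ValueError("param_table is empty")
    if len(param_table) != config.n_subjects:
        raise ValueError(
            f"param_table has {len(param_table)} rows but config expects "
            f"{config.n_subjects} subjects"
        )
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if "subject" not in param_table.columns:
        param_table = param_table.assign(
            subject=np.arange(1, len(param_table) + 1)
        )
    frames = []
    for i, (_, row) in enumerate(param_table.iterrows(), start=1):
        params = params_from_row(row)
        designs = generate_designs(config, rng, subject=i)
        df = simulate_trials(params, designs, rng)
        df.insert(0, "subject", int(row.get("subject", i)))
        frames.append(df)
    full = pd.concat(frames, ignore_index=True)
    full["correct"] = full["correct"].astype(int)
    full["more_frequent_side"] = full["more_frequent_side"].fillna("NA")

    trials = full[PUBLIC_COLUMNS].copy()
    truth = full[LATENT_COLUMNS].copy()
    truth = truth.merge(param_table, on="subject", how="left")
    for key, value in asdict(config).items():
        if key in ("rt_deadline_ms", "feedback_block", "seed"):
            truth.attrs[key] = value
    return trials, truth
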