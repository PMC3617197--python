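"""Published per-subject parameter sets for the two gap-paradigm studies.

These are the fitted hybrid-model parameters of the ten subjects of the
unbiased experiment and the eleven subjects of the biased (65/35 cued)
experiment.  They serve as the default generating parameters for the
synthetic-experiment module: simulating the model at these values
reproduces the studies' headline behavioral summaries (grand-mean
accuracy, RT-vs-gap slope, critical raw processing time, and the
congruent/incongruent peak lag).

Columns: ``theta`` (transition threshold, evidence units out of the
fixed response threshold 1000), ``mu_int``/``sigma_int`` and
``mu_ext``/``sigma_ext`` (log-scale lognormal parameters of the internal
and external accumulation rates, evidence units/ms), ``exec_delay_ms``,
``A`` (interaction ramp duration, ms), and for the biased study
``alpha`` (internal choice bias toward the cued frequent side).
"""

from __future__ import annotations

import pandas as pd

from .params import HybridParams

__all__ = ["experiment1_params", "experiment2_params", "params_from_row"]

_EXP1 = [
    # subject, theta, mu_int, sigma_int, mu_ext, sigma_ext, exec_delay_ms, A
    (1, 552, 1.4, 1.4, 1.2, 0.3, 125, 21),
    (2, 493, 1.6, 1.0, 1.7, 0.4, 129, 11),
    (3, 404, 1.4, 1.1, 0.8, 0.5, 120, 76),
    (4, 428, 1.1, 0.9, 1.3, 0.4, 111, 81),
    (5, 528, 2.1, 1.4, 1.9, 0.4, 130, 10),
    (6, 559, 2.3, 1.3, 1.8, 0.4, 127, 21),
    (7, 502, 1.5, 1.5, 0.7, 0.4, 141, 73),
    (8, 491, 1.0, 1.7, 0.8, 0.4, 138, 8),
    (9, 498, 1.0, 1.4, 0.6, 0.3, 121, 106),
    (10, 427, 1.4, 1.2, 1.2, 0.5, 173, 12),
]

_EXP2 = [
    # subject, theta, mu_int, sigma_int, mu_ext, sigma_ext, exec_delay_ms, A, alpha
    (1, 427, 1.0, 1.3, 0.4, 0.4, 102, 5, 0.66),
    (2, 584, 1.6, 1.0, 1.2, 0.3, 130, 56, 0.62),
    (3, 830, 1.3, 1.1, 0.3, 0.3, 109, 81, 0.74),
    (4, 341, 0.6, 1.7, 0.8, 0.8, 103, 62, 0.71),
    (5, 623, 1.2, 0.6, 0.8, 0.3, 109, 31, 0.58),
    (6, 464, 1.1, 1.5, 1.2, 0.6, 102, 28, 0.73),
    (7, 300, 0.5, 1.2, 0.6, 0.3, 102, 12, 0.62),
    (8, 338, 0.9, 2.1, 0.6, 0.5, 102, 8, 0.60),
    (9, 525, 1.0, 1.0, 1.3, 0.4, 92, 103, 0.46),
    (10, 438, 1.1, 1.9, 2.1, 0.2, 102, 93, 0.56),
    (11, 382, 1.6, 1.3, 0.6, 0.4, 140, 81, 0.53),
]

_COLS = ["subject", "theta", "mu_int", "sigma_int", "mu_ext", "sigma_ext",
         "exec_delay_ms", "A"]


def experiment1_params() -> pd.DataFrame:
    """Parameter table of the ten unbiased-experiment subjects."""
    return pd.DataFrame(_EXP1, columns=_COLS)


def experiment2_params() -> pd.DataFrame:
    """Parameter table of the eleven biased-experiment subjects
    (includes the fitted internal-choice bias ``alpha``)."""
    return pd.DataFrame(_EXP2, columns=_COLS + ["alpha"])


def params_from_row(row: pd.Series) -> HybridParams:
    """Build a :class:`HybridParams` from one table row.

    ``alpha`` defaults to 0.5 when the column is absent.  An ``alpha``
    at the open boundary is nudged inside (0, 1) — irrelevant in
    practice since fitted biases lie well inside.
    """
    alpha = float(row["alpha"]) if "alpha" in row.index else 0.5
    return HybridParams(
        theta=float(row["theta"]),
        mu_int=float(row["mu_int"]),
        sigma_int=float(row["sigma_int"]),
        mu_ext=float(row["mu_ext"]),
        sigma_ext=float(row["sigma_ext"]),
        exec_delay=float(row["exec_delay_ms"]),
        accel=float(row["A"]),
        alpha=min(max(alpha, 1e-9), 1 - 1e-9),
    )
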