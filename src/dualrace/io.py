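"""Readers/writers for trial tables, parameter tables and run manifests.

Delimited text (comma or tab, auto-detected) with a header row; times in
milliseconds as floats; sides as single characters ``L``/``R`` (``NA``
for a missing more-frequent side).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .params import HybridParams
from .reference_params import params_from_row

logger = logging.getLogger("dualrace")

__all__ = ["SchemaError", "read_trials", "write_trials", "read_params_table",
           "write_params_table", "write_manifest"]

REQUIRED_TRIAL_COLUMNS = [
    "subject", "trial_id", "gap_ms", "rt_ms", "response_side",
    "target_side", "correct",
]
_NUMERIC = ["gap_ms", "rt_ms"]
_SIDE_COLUMNS = ["response_side", "target_side"]

PARAM_COLUMNS = ["subject", "theta", "mu_int", "sigma_int", "mu_ext",
                 "sigma_ext", "exec_delay_ms", "A"]


class SchemaError(ValueError):
    """A required column is missing or has an invalid layout."""


def _read_delimited(path: str | Path) -> pd.DataFrame:
    # sniff comma vs tab from the header, then parse with the C engine
    # (round_trip float parsing preserves written values exactly)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial table.

    Rows with unparseable numerics, non-positive RTs or invalid side
    codes are rejected (row numbers logged); extra columns are
    preserved.  Raises :class:`SchemaError` when a required column is
    missing entirely.
    """
    df = _read_delimited(path)
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    bad = pd.Series(False, index=df.index)
    for col in _NUMERIC:
        values = pd.to_numeric(df[col], errors="coerce")
        bad |= ~np.isfinite(values)
        df[col] = values
    bad |= df["rt_ms"] <= 0
    for col in _SIDE_COLUMNS:
        bad |= ~df[col].isin(["L", "R"])
    if "more_frequent_side" in df.columns:
        df["more_frequent_side"] = df["more_frequent_side"].where(
            df["more_frequent_side"].isin(["L", "R"]), None
        )
    else:
        df["more_frequent_side"] = None
    df["correct"] = pd.to_numeric(df["correct"], errors="coerce")
    bad |= ~df["correct"].isin([0, 1])

    if bad.any():
        rows = (bad[bad].index + 2).tolist()  # 1-based + header
        logger.warning("rejected %d invalid row(s) at file line(s) %s",
                       bad.sum(), rows)
    out = df[~bad].copy()
    out["correct"] = out["correct"].astype(int)
    if "rpt_ms" not in out.columns:
        out["rpt_ms"] = out["rt_ms"] - out["gap_ms"]
    return out


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    out = trials.copy()
    if "more_frequent_side" in out.columns:
        out["more_frequent_side"] = out["more_frequent_side"].fillna("NA")
    out.to_csv(path, index=False)


def read_params_table(path: str | Path) -> list[HybridParams]:
    """Read a per-subject parameter table into validated parameter sets.

    Layout: ``subject, theta, mu_int, sigma_int, mu_ext, sigma_ext,
    exec_delay_ms, A[, alpha]`` (``alpha`` defaults to 0.5).  Validation
    errors (e.g. a transition threshold at or above the response
    threshold, non-positive sigmas) raise ``ValueError``.
    """
    df = _read_delimited(path)
    missing = [c for c in PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return [params_from_row(row) for _, row in df.iterrows()]


def write_params_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_manifest(
    out_dir: str | Path,
    config: dict[str, Any],
    seed: int | None,
    name: str = "manifest.json",
) -> Path:
    """Write a reproducibility manifest (config echo + hash, seed,
    package version) next to a run's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
    }
    path = out_dir / name
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
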