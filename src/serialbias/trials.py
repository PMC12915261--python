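"""The per-trial table contract shared across the package.

A trial table is a pandas DataFrame with (at least) the columns

    trial            1-based integer trial index, strictly increasing
                     within a condition
    condition        "high_auto" or "no_auto"
    stimulus_log     log stimulus distance (dimensionless, cm / 1 cm)
    reproduction_log log reproduced distance (NaN when undefined)
    error_log        reproduction_log - stimulus_log
    valid            boolean inclusion flag
    direction        optional "left"/"right" (may be missing/NA)

Extra columns (e.g. exclusion flags carried from raw data) are allowed and
preserved by all operations.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .sequences import CONDITIONS

__all__ = ["TRIAL_COLUMNS", "new_trial_table", "validate_trial_table",
           "read_trials_csv", "write_trials_csv"]

TRIAL_COLUMNS = [
    "trial",
    "condition",
    "stimulus_log",
    "reproduction_log",
    "error_log",
    "valid",
    "direction",
]


def new_trial_table(
    stimulus_log,
    reproduction_log,
    condition: str,
    valid=None,
    direction=None,
    trial=None,
) -> pd.DataFrame:
    """Assemble a trial table; ``error_log`` is derived, never supplied."""
    s = np.asarray(stimulus_log, dtype=float)
    r = np.asarray(reproduction_log, dtype=float)
    if s.shape != r.shape or s.ndim != 1:
        raise ValueError("stimulus_log and reproduction_log must be equal-length 1-D")
    n = len(s)
    table = pd.DataFrame(
        {
            "trial": np.arange(1, n + 1) if trial is None else np.asarray(trial, dtype=int),
            "condition": condition,
            "stimulus_log": s,
            "reproduction_log": r,
            "error_log": r - s,
            "valid": np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool),
            "direction": pd.array([None] * n if direction is None else direction, dtype="object"),
        }
    )
    validate_trial_table(table)
    return table


def validate_trial_table(table: pd.DataFrame) -> None:
    """Check the trial-table contract; raise ValueError on violation."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad = set(table["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition values: {sorted(bad)}")
    for cond, group in table.groupby("condition", sort=False):
        t = group["trial"].to_numpy()
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError(f"trial indices not strictly increasing in {cond!r}")
    valid = table["valid"].to_numpy(dtype=bool)
    err = (table["reproduction_log"] - table["stimulus_log"] - table["error_log"]).to_numpy()
    if np.any(err[valid] != 0.0):
        raise ValueError("error_log must equal reproduction_log - stimulus_log")


def write_trials_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(Path(path), index=False, float_format="%.17g")


def read_trials_csv(path) -> pd.DataFrame:
    table = pd.read_csv(Path(path), float_precision="round_trip")
    if "valid" in table.columns:
        table["valid"] = table["valid"].astype(bool)
    if "direction" not in table.columns:
        table["direction"] = pd.array([None] * len(table), dtype="object")
    validate_trial_table(table)
    return table
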