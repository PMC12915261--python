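"""Ingestion of raw trial tables and the exclusion rules.

Raw trials carry linear-scale distances in cm plus behavioural flags.
``compute_log_errors`` converts them to the log-scale trial-table contract
(distances are divided by a 1 cm reference before the log, so the values
are dimensionless), and ``apply_exclusions`` marks invalid the trials
where the participant started the reproduction too early, moved in the
wrong direction, or reproduced less than 1 cm.

Validity is the only thing exclusions touch: stimulus and reproduction
values are never altered, and applying the rules twice is a no-op.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .trials import validate_trial_table

__all__ = ["RAW_COLUMNS", "read_raw_csv", "compute_log_errors", "apply_exclusions"]

logger = logging.getLogger(__name__)

RAW_COLUMNS = [
    "trial",
    "condition",
    "direction",
    "stimulus_cm",
    "reproduced_cm",
    "started_early",
    "wrong_direction",
]

_FLAG_COLUMNS = ["started_early", "wrong_direction"]


def read_raw_csv(path) -> pd.DataFrame:
    """Read a raw trial CSV; missing flag columns are treated as all-false."""
    raw = pd.read_csv(Path(path))
    required = ["trial", "condition", "stimulus_cm", "reproduced_cm"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"raw table missing columns: {missing}")
    for flag in _FLAG_COLUMNS:
        if flag not in raw.columns:
            raw[flag] = False
        else:
            raw[flag] = raw[flag].fillna(False).astype(bool)
    if "direction" not in raw.columns:
        raw["direction"] = pd.array([None] * len(raw), dtype="object")
    return raw


def compute_log_errors(raw: pd.DataFrame) -> pd.DataFrame:
    """Convert raw cm distances to a log-scale trial table.

    ``stimulus_log = ln(stimulus_cm)`` and, for positive reproductions,
    ``reproduction_log = ln(reproduced_cm)``; the reproduction error is
    their difference (negative = undershoot, positive = overshoot).
    Trials with a nonpositive reproduced distance fall outside the log's
    domain: they get ``reproduction_log = NaN`` and are marked invalid.
    Behavioural flag columns are carried through for the exclusion step.

    Raises
    ------
    ValueError
        If any stimulus distance is nonpositive.
    """
    stim = np.asarray(raw["stimulus_cm"], dtype=float)
    repro = np.asarray(raw["reproduced_cm"], dtype=float)
    if np.any(~(stim > 0)):
        raise ValueError("all stimulus distances must be positive")
    positive = repro > 0
    reproduction_log = np.where(positive, np.log(np.where(positive, repro, 1.0)), np.nan)
    table = pd.DataFrame(
        {
            "trial": np.asarray(raw["trial"], dtype=int),
            "condition": raw["condition"].to_numpy(),
            "stimulus_log": np.log(stim),
            "reproduction_log": reproduction_log,
            "error_log": reproduction_log - np.log(stim),
            "valid": positive,
            "direction": raw.get("direction", pd.Series([None] * len(raw))).to_numpy(),
            "reproduced_cm": repro,
        }
    )
    for flag in _FLAG_COLUMNS:
        table[flag] = (
            raw[flag].fillna(False).astype(bool).to_numpy()
            if flag in raw.columns
            else False
        )
    validate_trial_table(table)
    return table


def apply_exclusions(table: pd.DataFrame, min_reproduced_cm: float = 1.0) -> pd.DataFrame:
    """Mark invalid the trials matching any exclusion rule.

    A trial is excluded when the participant initiated the reproduction too
    early, moved in the wrong direction, or reproduced a distance shorter
    than ``min_reproduced_cm`` (default 1 cm, evaluated on the signed
    reproduced distance).  All other trials are untouched, so the operation
    is idempotent.  Exclusion counts are logged per rule.
    """
    if min_reproduced_cm <= 0:
        raise ValueError("min_reproduced_cm must be positive")
    validate_trial_table(table)
    out = table.copy()
    n = len(out)
    early = out["started_early"].to_numpy(dtype=bool) if "started_early" in out else np.zeros(n, bool)
    wrong = out["wrong_direction"].to_numpy(dtype=bool) if "wrong_direction" in out else np.zeros(n, bool)
    if "reproduced_cm" in out.columns:
        short = out["reproduced_cm"].to_numpy(dtype=float) < min_reproduced_cm
    else:
        # log-only table: compare on the log scale
        with np.errstate(invalid="ignore"):
            short = ~(out["reproduction_log"].to_numpy() >= math.log(min_reproduced_cm))
    excluded = early | wrong | short
    out["valid"] = out["valid"].to_numpy(dtype=bool) & ~excluded
    logger.info(
        "exclusions: %d early start, %d wrong direction, %d short reproduction; %d/%d valid",
        int(early.sum()), int(wrong.sum()), int(short.sum()), int(out["valid"].sum()), n,
    )
    return out
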