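"""Synthetic observer: reproductions with known biases.

The "static" observer reproduces a weighted mixture of the current
stimulus and the grand mean of all stimuli,

    r_t = w * s_t + (1 - w) * mean(s) + eps_t,

all on the log scale.  Its built-in central tendency is c = 1 - w and its
built-in serial dependence is exactly zero: the reproduction never depends
on the previous stimulus.  Data simulated from this model therefore make a
clean test bench for bias estimators — any nonzero serial-dependence
estimate is estimator bias, not behaviour.

The paired no-autocorrelation condition is built by jointly shuffling the
(stimulus, reproduction) pairs of a simulated session, which preserves
every per-trial error while destroying the stimulus autocorrelation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sequences import (
    DEFAULT_MAX_ITER,
    DEFAULT_SHUFFLE_TOL,
    NO_AUTO,
    DistanceSequence,
    _search_permutation,
)
from .trials import new_trial_table, validate_trial_table

__all__ = ["simulate_static", "shuffle_pairs", "DEFAULT_NOISE_SD"]

#: Default reproduction-noise SD in log units — small relative to the
#: typical stimulus SD of a default random walk (~0.2).
DEFAULT_NOISE_SD = 0.05


def simulate_static(
    stimuli: DistanceSequence,
    w: float,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate reproductions from the static observer model.

    Parameters
    ----------
    stimuli : DistanceSequence
        Log-scale stimulus sequence; its condition tag is inherited.
    w : float in [0, 1]
        Stimulus weight.  ``w = 1`` reproduces veridically (central
        tendency c = 0); ``w = 0`` always reproduces the grand mean
        (c = 1).
    noise_sd : float
        SD of the additive Gaussian reproduction noise, log units.
    seed : int or None

    Returns
    -------
    pandas.DataFrame
        Trial table with all trials valid.
    """
    if not (0.0 <= w <= 1.0):
        raise ValueError("w must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    s = stimuli.values
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, len(s)) if noise_sd > 0 else np.zeros(len(s))
    r = w * s + (1.0 - w) * s.mean() + noise
    return new_trial_table(s, r, stimuli.condition)


def shuffle_pairs(
    table: pd.DataFrame,
    tol: float = DEFAULT_SHUFFLE_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = None,
) -> pd.DataFrame:
    """Jointly shuffle (stimulus, reproduction) pairs into a no-autocorrelation table.

    Whole trials are permuted together, so the multiset of per-trial errors
    is untouched; only the order — and hence the stimulus autocorrelation —
    changes.  Permutations are drawn until the stimulus sequence satisfies
    ``|r1| <= tol``.

    Parameters
    ----------
    table : pandas.DataFrame
        A complete (all-valid) single-condition trial table.
    tol, max_iter, seed
        As in :func:`serialbias.sequences.constrained_shuffle`.

    Returns
    -------
    pandas.DataFrame
        Permuted table, re-indexed 1..n, condition ``no_auto``.
    """
    validate_trial_table(table)
    if not table["valid"].all():
        raise ValueError("shuffle_pairs requires a complete table (all trials valid)")
    if table["condition"].nunique() != 1:
        raise ValueError("shuffle_pairs operates on a single condition")
    if tol <= 0:
        raise ValueError("tol must be positive")
    rng = np.random.default_rng(seed)
    idx = _search_permutation(table["stimulus_log"].to_numpy(), tol, max_iter, rng)
    out = table.iloc[idx].reset_index(drop=True)
    out["trial"] = np.arange(1, len(out) + 1)
    out["condition"] = NO_AUTO
    return out
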