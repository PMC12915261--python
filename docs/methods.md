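# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `serialbias`.

## Causal model of the task

Per trial `t`, the observable variables are the log-scale stimulus
distance `s[t]` and the log-scale reproduction error
`e[t] = ln(reproduced) − ln(stimulus)`.  The assumed causal structure is:

* `s[t-1] → s[t]` — present only in the high-autocorrelation (random-walk)
  condition, where each stimulus is generated from its predecessor;
* `s[t] → e[t]` — the central-tendency effect (CT);
* `s[t-1] → e[t]` — the lag-1 serial-dependence effect (SD₁);
* `e[t-1] → e[t]` — error carryover (slow states such as drifting gain or
  attention that correlate consecutive errors).

`causal_graph` encodes this as an explicit DAG (`build_experiment_graph`
for an n-trial chain, `window_graph` for the 3-trial sliding window
`t−2 … t` in which every path relevant to lag-1 identification lives; the
window also contains `s[t-2]`, which the lag-2 robustness model needs).
d-separation is decided by the standard two-phase reachability traversal
(ancestors of the conditioning set, then direction-tagged trail walking).
An exhaustive path-enumeration oracle and `networkx.is_d_separator` serve
as independent references in the test suite; the three implementations are
compared on tens of thousands of random DAGs of up to six nodes.

`single_door_valid` checks Pearl's single-door criterion: an adjustment
set `Z` identifies the coefficient of one edge `X → Y` iff `Z` contains no
descendant of `Y` and `Z` d-separates `X` from `Y` once that edge is
removed.  On the autocorrelated window graph, exhaustive enumeration over
subsets of `{s[t], s[t-1], e[t-1]}` shows `{s[t-1]}` (and its superset
`{s[t-1], e[t-1]}`, which opens no path) identifies CT, and
`{s[t], e[t-1]}` is the unique identifier of SD₁ — hence the single
combined regression

```
e[t] = β₀ + CT·s[t] + SD₁·s[t-1] + β₁·e[t-1] + ε .
```

In the shuffled condition (no stimulus-chain edges) CT needs no
adjustment and SD₁ needs only `e[t-1]`; the same combined model remains
valid, which is why one specification is used throughout.

## Stimulus sequences

Distances are divided by a 1 cm reference and natural-logged; all
analysis happens on that scale.

**Random walk** (`generate_random_walk`, defaults `n = 130`,
bounds 17–60 cm, step SD 0.08): the first value is the log-scale midpoint
`(ln 17 + ln 60)/2` (31.9 cm); each step adds a Gaussian shift.  The
bounds are enforced by **rejection**: an out-of-bounds shift is redrawn.
Alternatives (reflection, clipping) would distort the step distribution
near the bounds; rejection keeps the walk continuous and the steps
approximately Gaussian.  High lag-1 autocorrelation is the defining
design property of this condition, so by default candidate walks are
regenerated until `r₁ > 0.9` (`min_r1` parameter); at the design length
of 130 trials roughly four of five candidates pass immediately, while
short walks rarely can (disable with `min_r1=None`).  Optional
`mean_range`/`sd_range` filters mirror per-participant descriptive ranges
but are off by default — they are observations, not design constraints.

**Lag-1 autocorrelation** (`lag1_autocorrelation`):

```
r₁ = (1/N) Σ_{t=1}^{N−1} (y_t − ȳ)(y_{t+1} − ȳ) / c₀
```

with `c₀` the 1/N-normalized (population) sample variance.  The matching
normalizations make `r₁` the standard sample autocorrelation and bound it
in [−1, 1].  A constant sequence (c₀ = 0) raises a degenerate-input
error.

**Constrained shuffle** (`constrained_shuffle`): uniform random
permutations are drawn until `|r₁| ≤ tol` (default 0.001; budget 10⁶
draws).  For a 130-value walk, `r₁` of a random permutation is roughly
Normal(−1/N, 1/√N), so the acceptance region is hit within a few hundred
draws.  Failure reports the best `|r₁|` found; some inputs fail
deterministically (every permutation of two distinct values has
`r₁ = −1/2`).

## Synthetic observer

`simulate_static` implements `r_t = w·s_t + (1−w)·mean(s) + ε_t` with
`ε ~ Normal(0, noise_sd)`: built-in central tendency `c = 1 − w`, built-in
serial dependence exactly zero.  `noise_sd` defaults to 0.05 log units —
small relative to the typical stimulus SD of a default walk (~0.2), so
that coefficient means across replicates are insensitive to it while the
regression designs stay full rank.  With `noise_sd = 0` and `w = 1` all
errors are exactly zero: the two simple regressions return exactly zero
bias, and the MLR correctly refuses to fit (its `e[t-1]` regressor is
constant, i.e. collinear with the intercept).

`shuffle_pairs` builds the paired no-autocorrelation condition by jointly
permuting whole trials until the stimulus sequence meets the same
`|r₁| ≤ 0.001` tolerance, preserving the (stimulus, error) multiset
exactly.  This mirrors the simulation design; in a real experiment the
shuffled condition is responded to afresh, which is why the API keeps the
two pathways (`constrained_shuffle` of stimuli vs `shuffle_pairs` of
simulated trials) distinct.

## Estimation

Design rows (`build_design`) pair each trial with its physically previous
trial(s): a row exists only when the trial and all required lagged trials
are valid and consecutive (trial indices differing by 1) within one
condition.  Trials following an exclusion therefore contribute no row —
serial dependence is defined on the immediately preceding stimulus, and
bridging gaps would change the estimand.  Each condition is fit
separately; its first trial (first two for the lag-2 model) contributes
no row.

OLS is solved by singular-value decomposition with a rank check at
relative tolerance 1e−10.  Under high autocorrelation `s_t` and `s_{t−1}`
are strongly correlated (the added-variable spread of `s_t` shrinks), so
near-collinearity deserves an explicit diagnostic — on rank deficiency a
pivoted QR names the offending regressors — rather than a silently
pseudo-inverted solution.  Tests verify agreement with a direct
normal-equations solve (1e−10) and with `statsmodels.OLS`.

`partial_regression` residualizes the focal regressor and the response on
the remaining regressors; by the Frisch–Waugh–Lovell theorem the
residual-on-residual slope equals the corresponding multiple-regression
coefficient (asserted to 1e−8), and the residual pairs are the
added-variable plot coordinates.

`fit_lag2_check` fits `e_t = β₀ + β₁·s_{t−2} + β₂·s_{t−1} + β₃·e_{t−1} + ε`
and reports `β₁` with its standard error and two-sided p-value.  The
causal graph implies `e_t ⊥ s_{t−2} | {s_{t−1}, e_{t−1}}`, so `β₁ ≈ 0` on
data the model describes; an injected `s_{t−2}` effect is recovered (both
properties are verified by simulation in the test suite).

## Simulation study

`run_table1` runs, per stimulus weight `w ∈ {0, 0.5, 1}` and replicate:
generate a walk (130 trials), simulate the static observer, build the
shuffled-pairs condition, fit SLR-CT, SLR-SD₁ and the MLR in both
conditions; cell values are means over 1000 replicates (≈ 45 s on one
CPU; the test suite runs it at full scale).  Per-replicate seeds come
from spawning a master `SeedSequence`, making the study deterministic yet
replicate-independent.  A replicate aborted by a fit error is counted;
more than 1% failures aborts the study (none occur at the default
settings).  Expected pattern: CT = −(1−w) for every method and condition;
SD₁ = 0 everywhere except SLR under high autocorrelation, where it is
≈ −0.48 (w = 0.5) and ≈ −0.95 (w = 0).

Group-level statistics (for real multi-participant tables): two-sided
paired and one-sample t-tests with Cohen's d (paired d uses the SD of the
pairwise differences — the standard pairing convention; the tests' 95%
CIs are for the mean (difference)), and a Wilcoxon rank-sum test with
rank-biserial correlation `2U₁/(n₁n₂) − 1` for the movement-direction
check on unsigned errors.  Identical paired samples have zero-variance
differences and raise a degenerate-input error rather than returning an
undefined statistic.

## Preprocessing of real data

Raw tables carry cm-scale distances plus flags.  Log errors are computed
as above; a nonpositive reproduced distance is outside the log's domain
and marks the trial invalid.  Exclusions (early start, wrong direction,
reproduced distance < 1 cm — evaluated on the signed distance) only flip
the `valid` flag, never values, and are idempotent.  The end-position
correction applied to motion-platform speed traces in the original
paradigm operates on hardware signals outside this data model; reproduced
distances are accepted as given.

## What the synthetic data do and do not show

The generator reproduces the *design* of the experiment (sequence
statistics, trial counts, paired conditions) and an observer with known
ground-truth biases, which is exactly what is needed to measure estimator
bias.  It does not emulate perceptual/motor noise structure, learning or
fatigue, direction effects, or genuine serial dependence; passing tests
therefore certify the estimators, not any claim about real observers.
Real datasets enter through the raw-CSV contract and flow through the
identical estimation path, but their coefficient values are not asserted
anywhere.

## Numerical conventions

* Natural logs throughout; log-range 2.833–4.094 for 17–60 cm.
* Population (1/N) normalization for sequence SD and `c₀`, matching the
  `r₁` formula.
* CSV floats are written with `%.17g` and read with round-trip precision,
  so tables survive disk round-trips bit-exactly (the trial-table
  contract checks `error_log = reproduction_log − stimulus_log` exactly).
* `r_squared` is clamped to [0, 1]; a response with zero variance reports
  `r_squared = 0`.
* Randomness: every public generator takes a `seed` (int or
  `SeedSequence`); the study spawns child seeds counter-style from its
  master seed.

## Limitations

* The MLR identifies direct effects only under the assumed graph; latent
  confounders between stimuli and errors, or effects at lags beyond those
  modeled, are out of scope (the lag-2 check probes the first of these
  extensions, and general back-door/do-calculus machinery is deliberately
  not implemented).
* Estimation is per participant and per condition; no hierarchical
  pooling.
* The static observer is memoryless by construction; iterative (Kalman-
  style) observer models are not implemented.
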