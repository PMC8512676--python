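# Methods

## Model and assumptions

`calvingmc` models pre-calving behavior as a homogeneous first-order
Markov chain over five states (`L`, `LS`, `S`, `SL`, `CALVE`) at a uniform
time step. The assumptions, and what they buy:

* **First order.** The next behavior depends only on the current one. The
  co-occurrence matrix of adjacent pairs is then the sufficient statistic,
  and row normalization is the maximum-likelihood estimator of the
  transition matrix.
* **Time homogeneity.** One transition matrix describes the whole window.
  This is knowingly wrong near calving — restlessness increases — but it
  is what makes the closed-form fundamental-matrix solution available. The
  synthetic-cow generator (below) exists precisely to produce data that
  violate this assumption.
* **Absorbing calving.** `CALVE` has self-probability 1. Every quantity of
  interest (expected steps to absorption, absorption probability) follows
  from the canonical decomposition `A = [[Q, R], [O, I]]` and the
  fundamental matrix `N = (I − Q)⁻¹`.

The headline prediction statistic is the **grand sum of N** — the sum of
the expected absorption times over all four transient start states. For
the reference cows each per-start expectation is ≈ 1050–1080 minutes
(≈ 17–18 h), and their sum lands near 72 h, which is the reading the
evaluation protocol compares against the actual calving time. The package
also exposes the per-start row sums, which are the standard per-trajectory
expectation; users should be aware the two readings differ by a factor of
roughly the number of transient states.

## Parameters that matter

| parameter | default | units | why |
|-----------|---------|-------|-----|
| `step_minutes` | 1 | minutes | one Markov step; the reference matrices' totals (≈ 4320 pairs per 72 h) are only consistent with 1-minute steps, so 1 is the default even though coarser annotation grids (e.g. 5 min) are accepted |
| window (`hours_before_calving`) | none (72 or 48 typical) | hours | the suffix of observation used for estimation; the final 48 h carry most of the pre-calving signal |
| `zero_row_policy` | `error` | — | a state never left in the data has an undefined row; `self_loop` and `uniform` are available for exploratory work. The `CALVE` row is exempt: truthful counting always leaves it empty and the model defines it absorbing, so it becomes the unit self-loop |
| `p0_policy` | `first_state` | — | initial distribution for the absorption probability; `uniform` or an explicit vector over the transient states are accepted. With a single absorbing state the absorption probability is 1 regardless |
| `reference_hours` | 72 | hours | evaluation reference: the study design observes cows from 72 h before expected calving, so the actual event time is 72 h from observation start |
| simulator `seed` | 20210928 | — | all Monte Carlo entry points are seeded and record the seed in their outputs |
| simulator `max_steps` | 10⁶ | steps | truncation bound for near-singular chains; truncated paths are excluded from means with a logged count |

## Numerical choices

* **Fundamental matrix.** `N` solves `(I − Q) N = I` by LU factorization
  with partial pivoting — never an explicit inverse. Behavior chains have
  `diag(Q)` close to 1, so `I − Q` is habitually ill-scaled; the 1-norm
  condition number is reported with every result and a warning is logged
  above 1e8. Transient states that cannot reach any absorbing state are
  detected by graph reachability before the solve and named in the error.
* **Tolerance ladder.** Row-stochasticity is enforced at 1e−12 for
  matrices the package computes; solver identities (`N(I−Q)=I`, row sums
  of `N·R`) are tested at 1e−8; comparisons against reference matrices
  transcribed at 3 decimal places use 0.0005 (same printed rounding) for
  probabilities and 0.01 for the expected-time sums.
* **Transcribed matrices.** Published probability matrices rounded to 3
  decimals can have rows summing to 0.999; the fixture loaders accept a
  2e−3 row-sum tolerance and offer exact renormalization for computations
  (simulation, matrix solves) that need true stochasticity.
* **Matrix powers.** `P^t` uses binary exponentiation
  (`numpy.linalg.matrix_power`); propagated distributions are clipped and
  renormalized to absorb float drift at large `t`.
* **Stationary distribution.** `π = πP` is solved by eigen-decomposition
  of `Pᵀ`. An absorbing chain is reducible, so its stationary distribution
  is degenerate — a point mass on `CALVE`; the result carries a
  `reducible` flag to make clear the long-run distribution says nothing
  about transient behavior. The function exists for completeness of the
  transient analysis, not for prediction.
* **Windowing.** `hours × 60 / step_minutes` must be a whole number of
  steps (relative tolerance 1e−9); otherwise the window is rejected rather
  than silently rounded.

## The simulator, and what the tests do and do not show

`simulate_sequence` draws paths state-by-state (one uniform per step) and
stops at `CALVE` or at `max_steps`; `estimate_absorption_time` runs
vectorized batches of paths and reports per-start mean steps, standard
errors, and the split over absorbing states. These are the independent
oracle for the matrix solutions: on the reference chains, simulated means
match the row sums of `(I − Q)⁻¹` within 3 standard errors at 20,000 paths
per start.

`make_synthetic_cow` generates 72 h sequences from a time-inhomogeneous
chain in which the `L` and `S` self-transition probabilities decay
linearly toward calving (mass moved into `LS` and `SL`), emulating
pre-calving restlessness. It emulates: a plausible drift in posture-change
frequency, reproducible per seed. It does not emulate: circadian structure
(feeding/milking peaks), bout-length distributions beyond geometric,
individual-cow heterogeneity, or observation noise from a posture
classifier. Passing tests on synthetic data therefore validate the
machinery and its statistical consistency, not field performance on real
barns.

## Design choices where the design was open

* **Grand sum as the prediction statistic.** The per-start row sums of `N`
  are the textbook expectation, but the evaluation protocol's published
  per-cow times are on the grand-sum scale, so that is what
  `predicted_hours` reports; both are exposed in every summary.
* **Counting is truthful; augmentation is explicit.** `count_transitions`
  records only observed pairs (zero `CALVE` row); making calving absorbing
  is a separate, idempotent `augment_absorbing` step. Published count
  matrices that already carry the absorbing convention in the `CALVE` row
  are accepted as-is by the readers.
* **Suffix windowing.** "Use 48 h of data" is interpreted as the final
  48 h before the end of observation, where the signal is; a prefix mode
  exists for sensitivity checks.
* **Sequences need not end in calving.** Prediction from an ongoing
  observation is the use case; only a mid-sequence `CALVE` is rejected.
* **Generic alphabets.** The behavior alphabet is the canonical five
  states, but the chain and absorbing machinery accept any state set
  (used by the two-state and gambler's-ruin test oracles).

## Problem sizes used in the shipped checks

Unit and property tests run on 4×4–5×5 matrices, sequences up to 10⁵
steps, 1,000 random substochastic matrices for the inverse identity, and
20,000 Monte Carlo paths per start state per reference chain; the full
suite completes in well under a minute on one core. The acceptance script
uses the packaged reference matrices plus one 80,000-path Monte Carlo
cross-check.

## Known limitations

* The published fundamental matrix for cow ID 2 was computed by the
  original authors from unrounded probabilities; it cannot be reproduced
  from the 3-decimal transition matrix they printed (the rounded matrix
  yields ≈ 4944 expected minutes versus the published 4253.3). The
  packaged `N` is therefore compared as published, not recomputed from the
  rounded `P`.
* Cow ID 2's published count matrix is internally inconsistent in its `LS`
  row (it implies 0.929 where the published probability is 0.890); only
  its `L` row is used for verification. ID 11 and ID 27 are fully
  self-consistent.
* The published diagonal-power table (drift of `p11`, `p33` with `t`) was
  also computed from unrounded probabilities; the package reproduces its
  qualitative shape — strict decay of the lying and standing diagonals —
  not its exact decimals.
* The homogeneous chain ignores the very drift that signals calving; the
  grand-sum statistic compensates in aggregate on the study's data but has
  no per-trajectory interpretation.
* Per-cow predictions for the 22 cows without published matrices require
  the original video-derived sequences, which are not public; the
  evaluation protocol is exercised on the published prediction table
  instead.
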