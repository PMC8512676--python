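"""Monte Carlo simulation of behavior-state chains.

Serves three roles: an independent check on the matrix solution for
expected absorption times, a test bed for transition-matrix recovery, and
a generator of synthetic cows — including a time-inhomogeneous variant
whose posture self-transition probabilities drift toward calving, which
the homogeneous model deliberately ignores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .absorbing import FundamentalMatrix, _trapped_states, canonical_decompose
from .chain import TransitionMatrix
from .core import ABSORBING_LABEL, STATE_LABELS, BehaviorSequence, InputError

__all__ = [
    "SimulationSpec",
    "SimulationResult",
    "StartSummary",
    "DriftParams",
    "simulate_sequence",
    "estimate_absorption_time",
    "make_synthetic_cow",
]

DEFAULT_SEED = 20210928
DEFAULT_MAX_STEPS = 10**6


@dataclass(frozen=True)
class SimulationSpec:
    """Inputs of a Monte Carlo run.

    ``start`` is a state label, or ``None`` to simulate from every
    transient state in turn (``n_paths`` replicates each).
    """

    P: TransitionMatrix
    start: str | None = None
    max_steps: int = DEFAULT_MAX_STEPS
    n_paths: int = 1
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise InputError("max_steps must be >= 1")
        if self.n_paths < 1:
            raise InputError("n_paths must be >= 1")


@dataclass(frozen=True)
class StartSummary:
    """Absorption-time statistics for one starting state."""

    start: str
    n_paths: int
    n_absorbed: int
    n_truncated: int
    mean_steps: float
    standard_error: float
    absorbing_split: dict[str, float]


@dataclass(frozen=True)
class SimulationResult:
    per_start: dict[str, StartSummary]
    absorbed_fraction: float
    seed: int
    max_steps: int
    expected_steps_by_start: dict[str, float] | None = None

    def to_dict(self) -> dict:
        out = {
            "seed": self.seed,
            "max_steps": self.max_steps,
            "absorbed_fraction": self.absorbed_fraction,
            "per_start": {
                k: {
                    "n_paths": v.n_paths,
                    "n_absorbed": v.n_absorbed,
                    "n_truncated": v.n_truncated,
                    "mean_steps": v.mean_steps,
                    "standard_error": v.standard_error,
                    "absorbing_split": v.absorbing_split,
                }
                for k, v in self.per_start.items()
            },
        }
        if self.expected_steps_by_start is not None:
            out["expected_steps_by_start"] = self.expected_steps_by_start
        return out


def _walk_path(
    cum_rows,
    stop: np.ndarray,
    start: int,
    max_steps: int,
    rng: np.random.Generator,
) -> list[int]:
    """One path, drawing a single uniform per step. ``cum_rows`` maps a
    step index and current state to that state's cumulative row; ``stop``
    marks states that terminate the walk."""
    path = [start]
    state = start
    for t in range(max_steps):
        if stop[state]:
            break
        u = rng.random()
        state = int(np.searchsorted(cum_rows(t, state), u, side="right"))
        path.append(state)
    return path


def simulate_sequence(spec: SimulationSpec) -> BehaviorSequence:
    """Draw one behavior sequence from a homogeneous chain.

    Successive states are sampled from the rows of P until an absorbing
    state (calving) is entered or ``max_steps`` steps have been taken.
    Requires the canonical five-state alphabet since the result is a
    :class:`BehaviorSequence`.
    """
    if tuple(spec.P.state_order) != STATE_LABELS:
        raise InputError(
            "simulate_sequence requires the canonical behavior alphabet"
        )
    if spec.start is None:
        raise InputError("simulate_sequence needs an explicit start state")
    rng = np.random.default_rng(spec.seed)
    cum = np.cumsum(spec.P.probs, axis=1)
    cum[:, -1] = 1.0  # guard against rounding shortfall in transcribed rows
    # observation stops at calving specifically; other self-loops keep going
    stop = np.zeros(spec.P.n_states, dtype=bool)
    stop[spec.P.index_of(ABSORBING_LABEL)] = True
    path = _walk_path(
        lambda t, s: cum[s], stop, spec.P.index_of(spec.start),
        spec.max_steps, rng,
    )
    return BehaviorSequence(np.array(path), step_minutes=1.0)


def _absorption_batch(
    P: np.ndarray,
    start: int,
    n_paths: int,
    max_steps: int,
    rng: np.random.Generator,
    absorbing_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized absorption times for ``n_paths`` paths from one start.

    Returns (steps of absorbed paths, final absorbing state of each,
    number of truncated paths).
    """
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    is_abs = np.zeros(P.shape[0], dtype=bool)
    is_abs[absorbing_idx] = True

    steps = np.zeros(n_paths, dtype=np.int64)
    finals = np.full(n_paths, -1, dtype=np.int64)
    alive = np.arange(n_paths)
    state = np.full(n_paths, start, dtype=np.int64)
    if is_abs[start]:
        return np.zeros(n_paths, dtype=np.int64), np.full(n_paths, start), 0
    cur = state
    t = 0
    while alive.size and t < max_steps:
        u = rng.random(alive.size)
        # one vectorized categorical draw per active path
        cur = (cum[cur] < u[:, None]).sum(axis=1)
        t += 1
        done = is_abs[cur]
        if done.any():
            steps[alive[done]] = t
            finals[alive[done]] = cur[done]
            alive = alive[~done]
            cur = cur[~done]
    n_trunc = int(alive.size)
    absorbed_mask = finals >= 0
    return steps[absorbed_mask], finals[absorbed_mask], n_trunc


def estimate_absorption_time(
    spec: SimulationSpec,
    fundamental: FundamentalMatrix | None = None,
) -> SimulationResult:
    """Monte Carlo estimate of the expected steps to absorption.

    For each starting state, ``n_paths`` independent paths are run until
    absorption or ``max_steps``; truncated paths are excluded from the
    mean with a warning. When a :class:`FundamentalMatrix` is supplied its
    row sums are attached for side-by-side comparison with the simulated
    means — the core cross-validation of the matrix solution.
    """
    D = canonical_decompose(spec.P, atol=1e-9)
    trapped = _trapped_states(D)
    if trapped:
        raise InputError(
            f"states {trapped} can never be absorbed; absorption time "
            "is undefined"
        )
    order = spec.P.state_order
    absorbing_idx = np.array([order.index(s) for s in D.absorbing_order])
    starts = (
        list(D.transient_order) if spec.start is None
        else [order[spec.P.index_of(spec.start)]]
    )
    rng = np.random.default_rng(spec.seed)
    per_start: dict[str, StartSummary] = {}
    total_paths = total_absorbed = 0
    for label in starts:
        steps, finals, n_trunc = _absorption_batch(
            spec.P.probs, order.index(label), spec.n_paths, spec.max_steps,
            rng, absorbing_idx,
        )
        n_abs = steps.size
        total_paths += spec.n_paths
        total_absorbed += n_abs
        if n_trunc:
            warnings.warn(
                f"{n_trunc} of {spec.n_paths} paths from {label} not "
                f"absorbed within {spec.max_steps} steps; excluded from mean",
                stacklevel=2,
            )
        mean = float(steps.mean()) if n_abs else float("nan")
        se = float(steps.std(ddof=1) / np.sqrt(n_abs)) if n_abs > 1 else float("nan")
        split = {
            s: float(np.mean(finals == order.index(s))) if n_abs else float("nan")
            for s in D.absorbing_order
        }
        per_start[label] = StartSummary(
            start=label, n_paths=spec.n_paths, n_absorbed=n_abs,
            n_truncated=n_trunc, mean_steps=mean, standard_error=se,
            absorbing_split=split,
        )
    expected = None
    if fundamental is not None:
        expected = {
            label: float(v)
            for label, v in zip(fundamental.transient_order,
                                fundamental.row_totals)
        }
    return SimulationResult(
        per_start=per_start,
        absorbed_fraction=total_absorbed / total_paths,
        seed=spec.seed,
        max_steps=spec.max_steps,
        expected_steps_by_start=expected,
    )


@dataclass(frozen=True)
class DriftParams:
    """Linear pre-calving drift of the posture self-transitions.

    Over the course of the simulated window, ``lying_drift`` is gradually
    moved from p(L, L) to p(L, LS) and ``standing_drift`` from p(S, S) to
    p(S, SL), ramping linearly from zero at the start to the full amount
    at the final step. This mimics the restlessness — more frequent
    posture changes — observed as calving approaches, and produces
    sequences that violate the homogeneity the model assumes.
    """

    lying_drift: float = 0.0
    standing_drift: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lying_drift <= 1.0
                and 0.0 <= self.standing_drift <= 1.0):
            raise InputError("drift parameters must be probabilities in [0, 1]")


def make_synthetic_cow(
    drift: DriftParams,
    seed: int,
    base: TransitionMatrix,
    hours: float = 72.0,
    step_minutes: float = 1.0,
) -> BehaviorSequence:
    """Generate a synthetic pre-calving behavior sequence.

    Simulates up to ``hours`` of observation at ``step_minutes`` steps from
    a time-inhomogeneous chain built on ``base`` (canonical alphabet), with
    the self-transition mass of L and S shifted linearly into LS and SL
    respectively per ``drift``. Stops early if calving is reached. With
    zero drift this reduces exactly to :func:`simulate_sequence` from L
    (same seed, same draws).
    """
    if tuple(base.state_order) != STATE_LABELS:
        raise InputError("make_synthetic_cow requires the canonical alphabet")
    P0 = base.probs
    drift_amount = np.array([
        min(drift.lying_drift, P0[0, 0]),
        min(drift.standing_drift, P0[2, 2]),
    ])
    max_steps = int(round(hours * 60.0 / step_minutes))
    rng = np.random.default_rng(seed)
    stop = np.zeros(base.n_states, dtype=bool)
    stop[base.index_of(ABSORBING_LABEL)] = True

    base_cum = np.cumsum(P0, axis=1)
    base_cum[:, -1] = 1.0

    def cum_rows(t: int, s: int) -> np.ndarray:
        if drift_amount[0] == 0.0 and drift_amount[1] == 0.0:
            return base_cum[s]
        frac = t / max(max_steps - 1, 1)
        row = P0[s].copy()
        if s == 0:   # L: lying mass leaks into the rising transition
            shift = frac * drift_amount[0]
            row[0] -= shift
            row[1] += shift
        elif s == 2:  # S: standing mass leaks into the lying-down transition
            shift = frac * drift_amount[1]
            row[2] -= shift
            row[3] += shift
        c = np.cumsum(row)
        c[-1] = 1.0
        return c

    path = _walk_path(cum_rows, stop, 0, max_steps, rng)
    return BehaviorSequence(np.array(path), step_minutes=step_minutes)
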