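"""Discrete-time Markov chain estimation and transient analysis.

Covers the homogeneous-chain machinery shared by all downstream analyses:
maximum-likelihood transition-matrix estimation by row normalization of the
pair counts, propagation of a state distribution p(t) = p(0) P^t, the
diagonal power trajectories used to visualise behavioral drift before
calving, and the stationary equation pi = pi P (which for an absorbing
chain degenerates to a point mass on the absorbing state).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from . import _matrixio
from .core import ABSORBING_LABEL, STATE_LABELS, InputError, NumericalError
from .counts import CooccurrenceMatrix

__all__ = [
    "TransitionMatrix",
    "StateDistribution",
    "StationaryDistribution",
    "row_normalize",
    "augment_absorbing",
    "propagate",
    "diagonal_trajectory",
    "stationary",
    "read_transition",
    "write_transition",
]

#: row-stochasticity tolerance for matrices built by this package
ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic matrix P of one-step transition probabilities.

    ``row_sum_tol`` controls how exactly rows must sum to one. Matrices
    produced by :func:`row_normalize` satisfy the default 1e-12; reference
    matrices transcribed at 3 decimal places need a looser tolerance
    (their rows can sum to 0.999) and are loaded with ``row_sum_tol=2e-3``.
    """

    probs: np.ndarray
    state_order: tuple[str, ...] = STATE_LABELS
    row_sum_tol: float = ROW_SUM_TOL

    def __post_init__(self) -> None:
        P = np.asarray(self.probs, dtype=float)
        k = len(self.state_order)
        if P.shape != (k, k):
            raise InputError(
                f"transition matrix must be {k}x{k}, got {P.shape}"
            )
        if np.any(P < -1e-15) or np.any(P > 1 + 1e-15):
            raise InputError("transition probabilities must lie in [0, 1]")
        bad = np.abs(P.sum(axis=1) - 1.0) > self.row_sum_tol
        if np.any(bad):
            labels = [self.state_order[i] for i in np.flatnonzero(bad)]
            raise InputError(
                f"rows {labels} do not sum to 1 within {self.row_sum_tol:g}"
            )
        object.__setattr__(self, "probs", P)

    @property
    def n_states(self) -> int:
        return len(self.state_order)

    def index_of(self, label: str) -> int:
        try:
            return self.state_order.index(label.upper())
        except ValueError:
            raise InputError(
                f"state {label!r} not in {self.state_order}"
            ) from None

    def absorbing_mask(self, atol: float = 1e-12) -> np.ndarray:
        """Boolean mask of absorbing states (self-probability 1)."""
        return np.abs(np.diag(self.probs) - 1.0) <= atol

    def renormalized(self) -> "TransitionMatrix":
        """Rescale each row to sum to exactly one.

        Useful when a matrix transcribed at fixed decimal precision must
        feed computations (simulation, fundamental matrix) that assume
        exact stochasticity.
        """
        P = self.probs / self.probs.sum(axis=1, keepdims=True)
        return TransitionMatrix(P, self.state_order)


@dataclass(frozen=True)
class StateDistribution:
    """Probability row vector p(t) over the states at step ``step_index``."""

    probs: np.ndarray
    step_index: int = 0
    state_order: tuple[str, ...] = STATE_LABELS

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(self.state_order),):
            raise InputError(
                f"distribution must have length {len(self.state_order)}"
            )
        if np.any(p < -1e-15):
            raise InputError("distribution entries must be nonnegative")
        if abs(p.sum() - 1.0) > ROW_SUM_TOL:
            raise InputError("distribution must sum to 1")
        if self.step_index < 0:
            raise InputError("step_index must be nonnegative")
        object.__setattr__(self, "probs", p)

    @classmethod
    def point_mass(
        cls, label: str, state_order: Sequence[str] = STATE_LABELS
    ) -> "StateDistribution":
        order = tuple(s.upper() for s in state_order)
        p = np.zeros(len(order))
        p[order.index(label.upper())] = 1.0
        return cls(p, 0, order)


@dataclass(frozen=True)
class StationaryDistribution:
    """A solution pi of pi = pi P with sum(pi) = 1.

    ``reducible`` flags chains whose transition graph is not strongly
    connected; there the solution concentrates on the recurrent states
    (for a single absorbing state: a point mass on it) and the transient
    states carry zero mass.
    """

    probs: np.ndarray
    residual: float
    reducible: bool
    state_order: tuple[str, ...] = STATE_LABELS


def row_normalize(
    C: CooccurrenceMatrix,
    zero_row_policy: str = "error",
    absorbing: str | None = ABSORBING_LABEL,
) -> TransitionMatrix:
    """Estimate P from counts: p(i, j) = c(i, j) / row_total(i).

    This is the maximum-likelihood estimator of a homogeneous first-order
    chain. A zero row has no data to normalize; the ``zero_row_policy``
    decides what happens:

    * ``'error'`` (default) — raise, naming the state;
    * ``'self_loop'`` — the state maps to itself with probability 1;
    * ``'uniform'`` — uniform over all states (exploratory use only).

    The designated ``absorbing`` state (CALVE) is exempt: truthful counting
    of a sequence that stops at calving always leaves that row empty, and
    the model defines it as absorbing, so a zero absorbing row becomes the
    unit self-loop regardless of policy.
    """
    counts = C.counts.astype(float)
    totals = counts.sum(axis=1)
    k = len(C.state_order)
    P = np.zeros((k, k))
    absorbing_idx = (
        C.state_order.index(absorbing.upper()) if absorbing is not None else None
    )
    for i in range(k):
        if totals[i] > 0:
            P[i] = counts[i] / totals[i]
        elif i == absorbing_idx:
            P[i, i] = 1.0
        elif zero_row_policy == "self_loop":
            P[i, i] = 1.0
        elif zero_row_policy == "uniform":
            P[i] = 1.0 / k
        elif zero_row_policy == "error":
            raise InputError(
                f"state {C.state_order[i]!r} was never left in the data "
                "(zero count row); set zero_row_policy to 'self_loop' or "
                "'uniform' to proceed"
            )
        else:
            raise InputError(f"unknown zero_row_policy {zero_row_policy!r}")
    return TransitionMatrix(P, C.state_order)


def augment_absorbing(
    P: TransitionMatrix, state: str = ABSORBING_LABEL
) -> TransitionMatrix:
    """Make ``state`` absorbing: its row becomes the unit self-loop.

    Idempotent; all other rows are untouched.
    """
    k = P.index_of(state)
    probs = P.probs.copy()
    probs[k] = 0.0
    probs[k, k] = 1.0
    return TransitionMatrix(probs, P.state_order, P.row_sum_tol)


def propagate(
    p0: StateDistribution, P: TransitionMatrix, t: int
) -> StateDistribution:
    """Transient distribution after t steps: p(t) = p(0) P^t."""
    if t < 0:
        raise InputError("step count t must be nonnegative")
    if p0.probs.shape[0] != P.n_states:
        raise InputError("distribution and matrix dimensions differ")
    # binary exponentiation; renormalize to absorb float drift in P**t
    pt = p0.probs @ np.linalg.matrix_power(P.probs, t)
    pt = np.clip(pt, 0.0, None)
    pt = pt / pt.sum()
    return StateDistribution(pt, p0.step_index + t, P.state_order)


def diagonal_trajectory(
    P: TransitionMatrix, steps: Sequence[int]
) -> pd.DataFrame:
    """Diagonal entries of P^t at the requested steps, transient states only.

    Raising the behavior matrix to growing powers and watching the diagonal
    is the drift diagnostic for an approaching calving: the self-transition
    probabilities of the postures (L, S) decay as probability mass leaks
    toward absorption, while the brief posture-transition states (LS, SL)
    stay near zero. Returns a table with column ``t`` plus one column per
    transient state, named ``p11`` ... ``p44`` by 1-based state position.
    """
    steps = [int(t) for t in steps]
    if any(t < 0 for t in steps):
        raise InputError("steps must be nonnegative")
    transient = np.flatnonzero(~P.absorbing_mask(atol=1e-9))
    cols = {f"p{i + 1}{i + 1}": [] for i in transient}
    for t in steps:
        Pt = np.linalg.matrix_power(P.probs, t)
        for i in transient:
            cols[f"p{i + 1}{i + 1}"].append(Pt[i, i])
    out = pd.DataFrame({"t": steps, **cols})
    return out


def stationary(P: TransitionMatrix, tol: float = 1e-10) -> StationaryDistribution:
    """Solve pi = pi P, sum(pi) = 1.

    The solution is the left eigenvector of P for eigenvalue 1. For a
    reducible chain — and an absorbing chain is always reducible — the
    equation can have several solutions; the eigen-solver then returns one
    supported on the recurrent states, and the result is flagged
    ``reducible`` so callers know the long-run distribution ignores the
    transient behavior states entirely.
    """
    n_comp, _ = connected_components(
        P.probs > 0, directed=True, connection="strong"
    )
    reducible = bool(n_comp > 1)

    vals, vecs = np.linalg.eig(P.probs.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    if abs(vals[idx] - 1.0) > 1e-8:
        raise NumericalError(
            f"no eigenvalue of P' near 1 (closest: {vals[idx]:.6g})"
        )
    pi = np.real(vecs[:, idx])
    pi = np.where(np.abs(pi) < 1e-14, 0.0, pi)
    if pi.sum() < 0:
        pi = -pi
    if np.any(pi < -1e-9):
        raise NumericalError("stationary eigenvector has negative entries")
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    residual = float(np.linalg.norm(pi - pi @ P.probs, 1))
    if residual > max(tol, 10 * P.row_sum_tol):
        raise NumericalError(
            f"stationary solve residual {residual:.3g} exceeds tolerance"
        )
    return StationaryDistribution(pi, residual, reducible, P.state_order)


def read_transition(
    source: str | IO[str], row_sum_tol: float = ROW_SUM_TOL
) -> TransitionMatrix:
    """Read a transition matrix from matrix-CSV (canonical labels)."""
    df = _matrixio.read_labeled_matrix(
        source, expected_rows=STATE_LABELS, expected_cols=STATE_LABELS
    )
    return TransitionMatrix(df.to_numpy(), STATE_LABELS, row_sum_tol)


def write_transition(P: TransitionMatrix, sink: str | IO[str]) -> None:
    """Write P as matrix-CSV. Full precision; display rounding to 3
    decimals is a presentation concern, not a storage one."""
    _matrixio.write_labeled_matrix(P.probs, P.state_order, P.state_order, sink)
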