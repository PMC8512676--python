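"""Absorbing-chain analysis: canonical form, fundamental matrix, expected
time to absorption.

With the states ordered transient-first, an absorbing chain's matrix takes
the canonical block form::

    A = [ Q  R ]
        [ O  I ]

where Q (m x m) holds transient-to-transient probabilities, R (m x r) the
transient-to-absorbing probabilities, O is zero and I the identity on the
r absorbing states. Because Q^t -> 0, the Neumann series I + Q + Q^2 + ...
converges to the fundamental matrix N = (I - Q)^-1, whose entry N(i, j) is
the expected number of visits to transient state j when starting in i
before absorption. Row sums of N are the expected steps to absorption per
starting state; the headline prediction statistic used here is the grand
sum of N over all entries — the sum of those per-start expectations —
interpreted in minutes when one step is one minute.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.sparse.csgraph import breadth_first_order

from .chain import StateDistribution, TransitionMatrix
from .core import InputError, NumericalError

__all__ = [
    "AbsorbingDecomposition",
    "FundamentalMatrix",
    "AbsorptionSummary",
    "canonical_decompose",
    "fundamental_matrix",
    "expected_time_by_start",
    "absorption_summary",
]

#: condition number above which the (I - Q) solve logs a warning;
#: behavior chains have diag(Q) near 1, so I - Q is habitually ill-scaled
COND_WARN_THRESHOLD = 1e8


@dataclass(frozen=True)
class AbsorbingDecomposition:
    """Canonical-form blocks of an absorbing chain."""

    Q: np.ndarray
    R: np.ndarray
    transient_order: tuple[str, ...]
    absorbing_order: tuple[str, ...]

    @property
    def m(self) -> int:
        """Number of transient states."""
        return len(self.transient_order)

    @property
    def r(self) -> int:
        """Number of absorbing states."""
        return len(self.absorbing_order)


@dataclass(frozen=True)
class FundamentalMatrix:
    """N = (I - Q)^-1 with its row sums and the conditioning of the solve."""

    N: np.ndarray
    row_totals: np.ndarray
    condition_estimate: float
    transient_order: tuple[str, ...]


@dataclass(frozen=True)
class AbsorptionSummary:
    """Expected time to absorption and the absorption probability.

    ``expected_steps_total`` is the grand sum of N over all entries (the
    sum of the per-start expected absorption times); ``expected_minutes``
    and ``expected_hours`` convert it with the step duration.
    ``absorption_prob`` is p(0) N R summed over absorbing states — the
    probability of ever being absorbed, which is 1 whenever every transient
    state reaches the single absorbing state.
    """

    expected_steps_total: float
    expected_steps_by_start: dict[str, float]
    expected_minutes: float
    expected_hours: float
    absorption_prob: float
    absorption_prob_by_state: dict[str, float]
    condition_estimate: float
    step_minutes: float

    def to_dict(self) -> dict:
        return {
            "expected_steps_total": self.expected_steps_total,
            "expected_steps_by_start": self.expected_steps_by_start,
            "expected_minutes": self.expected_minutes,
            "expected_hours": self.expected_hours,
            "absorption_prob": self.absorption_prob,
            "absorption_prob_by_state": self.absorption_prob_by_state,
            "condition_estimate": self.condition_estimate,
            "step_minutes": self.step_minutes,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def canonical_decompose(
    P: TransitionMatrix, atol: float = 1e-12
) -> AbsorbingDecomposition:
    """Partition P into the canonical blocks Q and R.

    Absorbing states are exactly those with self-probability 1 (within
    ``atol``). Canonical order is preserved within the transient and
    absorbing groups.
    """
    mask = P.absorbing_mask(atol)
    if not mask.any():
        raise InputError(
            "no absorbing state found (no diagonal entry equals 1); "
            "apply augment_absorbing first"
        )
    transient = np.flatnonzero(~mask)
    absorbing = np.flatnonzero(mask)
    if transient.size == 0:
        warnings.warn(
            "all states are absorbing: decomposition has an empty Q block",
            stacklevel=2,
        )
    Q = P.probs[np.ix_(transient, transient)]
    R = P.probs[np.ix_(transient, absorbing)]
    return AbsorbingDecomposition(
        Q=Q,
        R=R,
        transient_order=tuple(P.state_order[i] for i in transient),
        absorbing_order=tuple(P.state_order[i] for i in absorbing),
    )


def _trapped_states(D: AbsorbingDecomposition) -> list[str]:
    """Transient states from which no absorbing state is reachable."""
    m, r = D.m, D.r
    n = m + r
    adj = np.zeros((n, n), dtype=bool)
    adj[:m, :m] = D.Q > 0
    adj[:m, m:] = D.R > 0
    trapped = []
    for i in range(m):
        reached = breadth_first_order(
            adj, i_start=i, directed=True, return_predecessors=False
        )
        if not np.any(reached >= m):
            trapped.append(D.transient_order[i])
    return trapped


def fundamental_matrix(D: AbsorbingDecomposition) -> FundamentalMatrix:
    """Compute N = (I - Q)^-1 by an LU solve with partial pivoting.

    (I - Q) is near-singular when the chain dwells long in transient
    states (diagonal of Q near 1); a condition estimate is reported and a
    warning logged above 1e8. Explicit inversion is avoided in favor of
    solving (I - Q) N = I.
    """
    m = D.m
    if m == 0:
        return FundamentalMatrix(
            np.zeros((0, 0)), np.zeros(0), 1.0, D.transient_order
        )
    trapped = _trapped_states(D)
    if trapped:
        # a chain defect in the input, not a solver failure
        raise InputError(
            f"transient states {trapped} cannot reach any absorbing state; "
            "(I - Q) is singular"
        )
    ImQ = np.eye(m) - D.Q
    cond = float(np.linalg.cond(ImQ, 1))
    if cond > COND_WARN_THRESHOLD:
        warnings.warn(
            f"(I - Q) condition estimate {cond:.3g} exceeds "
            f"{COND_WARN_THRESHOLD:g}; expected times may lose precision",
            stacklevel=2,
        )
    try:
        lu, piv = lu_factor(ImQ)
        N = lu_solve((lu, piv), np.eye(m))
    except Exception as exc:  # singular despite reachability: numeric edge
        raise NumericalError(f"failed to solve (I - Q) N = I: {exc}") from exc
    return FundamentalMatrix(
        N=N,
        row_totals=N.sum(axis=1),
        condition_estimate=cond,
        transient_order=D.transient_order,
    )


def expected_time_by_start(F: FundamentalMatrix) -> dict[str, float]:
    """Expected steps to absorption from each transient start state.

    These are the row sums of N (equivalently the solution of
    (I - Q) t = 1).
    """
    return {
        label: float(v)
        for label, v in zip(F.transient_order, F.row_totals)
    }


def absorption_summary(
    F: FundamentalMatrix,
    D: AbsorbingDecomposition,
    p0: StateDistribution | np.ndarray | None = None,
    step_minutes: float = 1.0,
) -> AbsorptionSummary:
    """Summarise the absorbing-chain solution.

    ``p0`` is the initial distribution over the *transient* states (length
    m). ``None`` means uniform. A distribution over all states is accepted
    and restricted to the transient block; if the restriction does not sum
    to one it is renormalized with a warning.
    """
    m = D.m
    if p0 is None:
        p = np.full(m, 1.0 / m) if m else np.zeros(0)
    else:
        p = np.asarray(p0.probs if isinstance(p0, StateDistribution) else p0,
                       dtype=float)
        if p.shape == (m + D.r,):
            p = p[:m]  # canonical decomposition keeps transient states first
        if p.shape != (m,):
            raise InputError(
                f"p0 must have length {m} (transient states), got {p.shape}"
            )
        if np.any(p < 0):
            raise InputError("p0 entries must be nonnegative")
        s = p.sum()
        if abs(s - 1.0) > 1e-9:
            if s <= 0:
                raise InputError("p0 has zero total mass on transient states")
            warnings.warn(
                f"p0 mass on transient states is {s:.6g}; renormalizing",
                stacklevel=2,
            )
            p = p / s
    grand_sum = float(F.N.sum())
    by_start = expected_time_by_start(F)
    if m:
        b = p @ F.N @ D.R  # absorption probabilities per absorbing state
    else:
        b = np.zeros(D.r)
    minutes = grand_sum * step_minutes
    return AbsorptionSummary(
        expected_steps_total=grand_sum,
        expected_steps_by_start=by_start,
        expected_minutes=minutes,
        expected_hours=minutes / 60.0,
        absorption_prob=float(b.sum()),
        absorption_prob_by_state={
            label: float(v) for label, v in zip(D.absorbing_order, b)
        },
        condition_estimate=F.condition_estimate,
        step_minutes=step_minutes,
    )
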