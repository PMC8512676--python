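"""Co-occurrence (adjacent state pair) counting.

The first modelling step turns an observed behavior sequence into a 5x5
matrix C whose entry (i, j) counts how often state i was immediately
followed by state j. C is the sufficient statistic for the first-order
Markov chain; everything downstream is computed from it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np

from . import _matrixio
from .core import STATE_LABELS, BehaviorSequence, InputError

__all__ = [
    "CooccurrenceMatrix",
    "count_transitions",
    "read_cooccurrence",
    "write_cooccurrence",
]


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Nonnegative integer matrix of adjacent state-pair counts.

    Counting is truthful: a sequence that ends at calving contributes no
    pair leaving CALVE, so the CALVE row is all zeros. Published reference
    matrices instead carry the absorbing convention ``[0,0,0,0,1]`` in that
    row; :func:`read_cooccurrence` accepts either.
    """

    counts: np.ndarray
    state_order: tuple[str, ...] = STATE_LABELS

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        k = len(self.state_order)
        if counts.shape != (k, k):
            raise InputError(
                f"count matrix must be {k}x{k} for states {self.state_order}, "
                f"got shape {counts.shape}"
            )
        if not np.all(np.isfinite(counts)):
            raise InputError("count matrix contains non-finite entries")
        if np.any(counts < 0):
            raise InputError("count matrix entries must be nonnegative")
        if not np.all(counts == np.round(counts)):
            raise InputError("count matrix entries must be integers")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __add__(self, other: "CooccurrenceMatrix") -> "CooccurrenceMatrix":
        if self.state_order != other.state_order:
            raise InputError("cannot add counts over different state orders")
        return CooccurrenceMatrix(self.counts + other.counts, self.state_order)


def count_transitions(seq: BehaviorSequence) -> CooccurrenceMatrix:
    """Count adjacent state pairs (s_t, s_{t+1}) of a sequence.

    The entries sum to ``len(seq) - 1``: every adjacent pair is counted
    exactly once.
    """
    if len(seq) < 2:
        raise InputError(
            "need at least 2 states to count a transition pair, "
            f"got {len(seq)}"
        )
    k = len(STATE_LABELS)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (seq.codes[:-1], seq.codes[1:]), 1)
    return CooccurrenceMatrix(counts)


def read_cooccurrence(source: str | IO[str]) -> CooccurrenceMatrix:
    """Read a 5x5 co-occurrence matrix from matrix-CSV.

    Rows and columns must carry the canonical labels
    ``L, LS, S, SL, CALVE`` in order; cells must be nonnegative integers.
    """
    df = _matrixio.read_labeled_matrix(
        source, expected_rows=STATE_LABELS, expected_cols=STATE_LABELS
    )
    return CooccurrenceMatrix(df.to_numpy())


def write_cooccurrence(C: CooccurrenceMatrix, sink: str | IO[str]) -> None:
    _matrixio.write_labeled_matrix(
        C.counts, C.state_order, C.state_order, sink
    )
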