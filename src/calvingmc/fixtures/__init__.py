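"""Packaged reference matrices from the 25-cow calving study.

Three cows (ID 2, ID 11, ID 27) have published co-occurrence and
transition matrices; ID 2 additionally has the published canonical blocks
Q and R and the fundamental matrix N, and a 25-row table of per-cow
predicted calving times under 72 h and 48 h observation windows.

All matrices are transcribed at the published 3-decimal precision. Two
published quirks matter for testing:

* the probability matrices were rounded for publication, so a row can sum
  to 0.999; the loaders use a relaxed row-sum tolerance, and
  ``renormalize=True`` rescales rows for computations that need exact
  stochasticity (simulation, fundamental matrix);
* the published N for ID 2 was computed from unrounded probabilities and
  is *not* reproducible from the rounded P for ID 2.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .._matrixio import read_labeled_matrix
from ..chain import TransitionMatrix
from ..core import STATE_LABELS
from ..counts import CooccurrenceMatrix, read_cooccurrence

__all__ = [
    "COUNT_COWS",
    "TRANSITION_COWS",
    "load_counts",
    "load_transition",
    "load_canonical_blocks_id2",
    "load_fundamental_id2",
    "load_predictions",
]

#: cows with packaged co-occurrence counts (ID 2's LS row is known-inconsistent
#: with its published P; ID 11 and ID 27 are fully self-consistent)
COUNT_COWS = ("ID2", "ID11", "ID27")
#: cows with packaged transition matrices
TRANSITION_COWS = ("ID2", "ID11", "ID27")

TRANSIENT_LABELS = ("L", "LS", "S", "SL")

#: row-sum tolerance for matrices published at 3 decimals
PRINTED_ROW_SUM_TOL = 2e-3


def _data(name: str):
    return resources.files(__package__).joinpath("data", name)


def load_counts(cow: str) -> CooccurrenceMatrix:
    """Published co-occurrence matrix for ``cow`` in ``COUNT_COWS``."""
    cow = cow.upper()
    if cow not in COUNT_COWS:
        raise KeyError(f"no packaged counts for {cow!r}; have {COUNT_COWS}")
    with resources.as_file(_data(f"C_{cow}.csv")) as path:
        return read_cooccurrence(str(path))


def load_transition(cow: str, renormalize: bool = False) -> TransitionMatrix:
    """Published transition matrix for ``cow`` in ``TRANSITION_COWS``.

    With ``renormalize=True`` each row is rescaled to sum to exactly one,
    which simulation and fundamental-matrix computations require.
    """
    cow = cow.upper()
    if cow not in TRANSITION_COWS:
        raise KeyError(
            f"no packaged transition matrix for {cow!r}; have {TRANSITION_COWS}"
        )
    with resources.as_file(_data(f"P_{cow}.csv")) as path:
        df = read_labeled_matrix(
            str(path), expected_rows=STATE_LABELS, expected_cols=STATE_LABELS
        )
    P = TransitionMatrix(df.to_numpy(), STATE_LABELS,
                         row_sum_tol=PRINTED_ROW_SUM_TOL)
    return P.renormalized() if renormalize else P


def load_canonical_blocks_id2() -> tuple[np.ndarray, np.ndarray]:
    """Published canonical blocks (Q, R) for cow ID 2.

    Q is 4x4 over (L, LS, S, SL); R is a 4x1 column of calving
    probabilities.
    """
    with resources.as_file(_data("Q_ID2.csv")) as path:
        q = read_labeled_matrix(str(path), expected_rows=TRANSIENT_LABELS,
                                expected_cols=TRANSIENT_LABELS)
    with resources.as_file(_data("R_ID2.csv")) as path:
        r = read_labeled_matrix(str(path), expected_rows=TRANSIENT_LABELS,
                                expected_cols=("CALVE",))
    return q.to_numpy(), r.to_numpy()


def load_fundamental_id2() -> tuple[np.ndarray, np.ndarray]:
    """Published fundamental matrix for cow ID 2.

    Returns ``(N, row_totals)``: the 4x4 matrix of expected visit counts
    and the published fifth column of row totals (expected minutes to
    calving from each start state).
    """
    with resources.as_file(_data("N_ID2.csv")) as path:
        df = read_labeled_matrix(
            str(path), expected_rows=TRANSIENT_LABELS,
            expected_cols=TRANSIENT_LABELS + ("ROW_TOTAL",),
        )
    values = df.to_numpy()
    return values[:, :4], values[:, 4]


def load_predictions() -> pd.DataFrame:
    """Published per-cow predicted calving times (hours) for both windows.

    Columns: ``cow_id``, ``predicted_72h``, ``predicted_48h``; 25 rows.
    """
    with resources.as_file(_data("table4_predictions.csv")) as path:
        return pd.read_csv(str(path), comment="#")
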