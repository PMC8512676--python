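"""Labeled matrix-CSV reading and writing.

Dialect: first column is named ``state`` and holds row labels; remaining
column headers are the destination-state labels. Lines starting with ``#``
are comments. Used for co-occurrence counts, transition probabilities and
fundamental matrices alike.
"""

from __future__ import annotations

from typing import IO, Sequence

import numpy as np
import pandas as pd

from .core import InputError

INDEX_COL = "state"


def read_labeled_matrix(
    source: str | IO[str],
    expected_rows: Sequence[str] | None = None,
    expected_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    df = pd.read_csv(source, comment="#")
    df.columns = [str(c).strip() for c in df.columns]
    if df.columns[0].lower() != INDEX_COL:
        raise InputError(
            f"matrix-CSV must start with a '{INDEX_COL}' label column, "
            f"got {df.columns[0]!r}"
        )
    df = df.set_index(df.columns[0])
    df.index = [str(i).strip().upper() for i in df.index]
    df.columns = [str(c).strip().upper() for c in df.columns]
    if expected_rows is not None:
        want = [s.upper() for s in expected_rows]
        if list(df.index) != want:
            raise InputError(
                f"matrix-CSV rows {list(df.index)} do not match expected {want}"
            )
    if expected_cols is not None:
        want = [s.upper() for s in expected_cols]
        if list(df.columns) != want:
            raise InputError(
                f"matrix-CSV columns {list(df.columns)} do not match expected {want}"
            )
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise InputError(f"non-numeric matrix entry: {exc}") from None
    if not np.all(np.isfinite(values)):
        raise InputError("matrix-CSV contains non-finite entries")
    return pd.DataFrame(values, index=df.index, columns=df.columns)


def write_labeled_matrix(
    values: np.ndarray,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    sink: str | IO[str],
    float_format: str | None = None,
) -> None:
    df = pd.DataFrame(np.asarray(values), index=list(row_labels),
                      columns=list(col_labels))
    df.index.name = INDEX_COL
    df.to_csv(sink, float_format=float_format)
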