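"""Behavior state alphabet, sequences and windowing.

The model observes a pregnant cow in one of five behavior states at a
uniform time step:

* ``L``  — lying,
* ``LS`` — rising (lying-to-standing transition posture),
* ``S``  — standing,
* ``SL`` — lying down (standing-to-lying transition posture),
* ``CALVE`` — the calving event, which terminates observation.

The canonical state ordering is ``[L, LS, S, SL, CALVE]``; every matrix in
this package is indexed in that order unless it carries an explicit
``state_order``. Internally states are 0-based integer codes; user-facing
output uses labels (and, where an index is displayed, 1-based positions).
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATE_LABELS",
    "ABSORBING_LABEL",
    "BehaviorState",
    "BehaviorSequence",
    "TimeWindow",
    "InputError",
    "NumericalError",
    "parse_sequence",
    "write_sequence",
    "window_sequence",
]

STATE_LABELS: tuple[str, ...] = ("L", "LS", "S", "SL", "CALVE")
ABSORBING_LABEL = "CALVE"

#: seconds of jitter tolerated between timestamp spacings in dialect-B files
_TIMESTAMP_TOL_S = 1.0


class InputError(ValueError):
    """Invalid user input: parse failures, violated preconditions."""


class NumericalError(RuntimeError):
    """Numerical failure: singular systems, non-convergent solves."""


class BehaviorState(enum.IntEnum):
    """One of the five behavior states, with its canonical 0-based index."""

    L = 0
    LS = 1
    S = 2
    SL = 3
    CALVE = 4

    @property
    def label(self) -> str:
        return self.name

    @property
    def index(self) -> int:
        return int(self)

    @classmethod
    def from_label(cls, token: str) -> "BehaviorState":
        try:
            return cls[token.strip().upper()]
        except KeyError:
            raise InputError(
                f"unknown behavior state {token!r}; expected one of {STATE_LABELS}"
            ) from None


@dataclass(frozen=True)
class TimeWindow:
    """An observation window of ``hours_before_calving`` hours ending at the
    terminal state of a sequence."""

    hours_before_calving: float

    def __post_init__(self) -> None:
        if not self.hours_before_calving > 0:
            raise InputError("hours_before_calving must be positive")

    def n_steps(self, step_minutes: float) -> int:
        """Number of whole Markov steps the window spans."""
        raw = self.hours_before_calving * 60.0 / step_minutes
        steps = round(raw)
        if abs(raw - steps) > 1e-9 * max(1.0, abs(raw)):
            raise InputError(
                f"window of {self.hours_before_calving} h is not a whole number "
                f"of {step_minutes}-minute steps"
            )
        return int(steps)


@dataclass(frozen=True)
class BehaviorSequence:
    """An ordered behavior-state sequence at a uniform time step.

    Parameters
    ----------
    codes
        Integer state codes in canonical order (0=L ... 4=CALVE).
    step_minutes
        Duration of one step, in minutes. The worked examples in this
        package use 1-minute steps.
    origin_time
        Optional timestamp of the first observation.
    """

    codes: np.ndarray
    step_minutes: float = 1.0
    origin_time: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 1 or codes.size < 1:
            raise InputError("a behavior sequence needs at least one state")
        if codes.min(initial=0) < 0 or codes.max(initial=0) >= len(STATE_LABELS):
            raise InputError("state codes out of range")
        if not self.step_minutes > 0:
            raise InputError("step_minutes must be positive")
        calve = int(BehaviorState.CALVE)
        where = np.flatnonzero(codes == calve)
        if where.size and (where.size > 1 or where[0] != codes.size - 1):
            raise InputError(
                "CALVE may occur only as the final state (observation stops "
                "at calving)"
            )

    @classmethod
    def from_labels(
        cls,
        labels: Iterable[str],
        step_minutes: float = 1.0,
        origin_time: pd.Timestamp | None = None,
    ) -> "BehaviorSequence":
        codes = np.array([BehaviorState.from_label(s) for s in labels], dtype=np.int64)
        return cls(codes, step_minutes, origin_time)

    @property
    def labels(self) -> list[str]:
        return [STATE_LABELS[c] for c in self.codes]

    @property
    def states(self) -> list[BehaviorState]:
        return [BehaviorState(int(c)) for c in self.codes]

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def duration_minutes(self) -> float:
        """Span covered by the sequence: (length - 1) steps."""
        return (len(self) - 1) * self.step_minutes

    @property
    def duration_hours(self) -> float:
        return self.duration_minutes / 60.0

    @property
    def ends_in_calving(self) -> bool:
        return int(self.codes[-1]) == int(BehaviorState.CALVE)


def parse_sequence(
    source: str | IO[str],
    step_minutes: float | None = None,
) -> BehaviorSequence:
    """Read a behavior sequence from sequence-CSV.

    Two dialects are accepted (UTF-8, comma-separated, header required):

    * dialect A — a single column ``state``, one row per step;
      ``step_minutes`` must be supplied (default 1 when omitted);
    * dialect B — columns ``timestamp,state`` with uniformly spaced
      ISO-8601 timestamps; the spacing defines the step duration and must
      be constant to within one second.

    State tokens are matched case-insensitively and stripped of whitespace.
    """
    if isinstance(source, str) and "\n" not in source:
        df = pd.read_csv(source, dtype=str, skip_blank_lines=True, comment="#")
    else:
        buf = io.StringIO(source) if isinstance(source, str) else source
        df = pd.read_csv(buf, dtype=str, skip_blank_lines=True, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if "state" not in df.columns:
        raise InputError("sequence-CSV must have a 'state' column")
    if df.empty:
        raise InputError("sequence-CSV contains no data rows")

    origin = None
    if "timestamp" in df.columns:
        ts = pd.to_datetime(df["timestamp"])
        if len(ts) >= 2:
            deltas = ts.diff().dropna().dt.total_seconds().to_numpy()
            if deltas.min() <= 0:
                raise InputError("timestamps must be strictly increasing")
            if deltas.max() - deltas.min() > _TIMESTAMP_TOL_S:
                raise InputError(
                    "timestamps are not uniformly spaced (tolerance 1 s)"
                )
            inferred = float(np.median(deltas)) / 60.0
            if step_minutes is not None and abs(step_minutes - inferred) > 1 / 60:
                raise InputError(
                    f"step_minutes={step_minutes} conflicts with timestamp "
                    f"spacing of {inferred:.4g} min"
                )
            step_minutes = inferred
        origin = ts.iloc[0]
    if step_minutes is None:
        step_minutes = 1.0

    codes = np.empty(len(df), dtype=np.int64)
    for pos, token in enumerate(df["state"].tolist()):
        try:
            codes[pos] = BehaviorState.from_label(token)
        except InputError as exc:
            # +2: one for the header line, one for 1-based numbering
            raise InputError(f"line {pos + 2}: {exc}") from None
    return BehaviorSequence(codes, step_minutes, origin)


def write_sequence(seq: BehaviorSequence, sink: str | IO[str]) -> None:
    """Write a sequence as sequence-CSV (dialect B when an origin time is
    known, dialect A otherwise)."""
    if seq.origin_time is not None:
        times = seq.origin_time + pd.to_timedelta(
            np.arange(len(seq)) * seq.step_minutes, unit="m"
        )
        df = pd.DataFrame({"timestamp": times.strftime("%Y-%m-%dT%H:%M:%S"),
                           "state": seq.labels})
    else:
        df = pd.DataFrame({"state": seq.labels})
    df.to_csv(sink, index=False)


def window_sequence(
    seq: BehaviorSequence,
    window: TimeWindow,
    side: str = "suffix",
) -> BehaviorSequence:
    """Restrict a sequence to a time window.

    ``side='suffix'`` (default) keeps the final ``hours_before_calving``
    hours up to and including the terminal state — the behavior drift that
    signals calving intensifies as the event approaches, so the suffix is
    the informative part. ``side='prefix'`` keeps the start instead, for
    sensitivity checks.
    """
    n_steps = window.n_steps(seq.step_minutes)
    if n_steps > len(seq) - 1:
        raise InputError(
            f"window of {window.hours_before_calving} h ({n_steps} steps) "
            f"exceeds sequence duration of {seq.duration_hours:g} h"
        )
    if side == "suffix":
        codes = seq.codes[len(seq) - 1 - n_steps:]
        origin = None
        if seq.origin_time is not None:
            offset = (len(seq) - 1 - n_steps) * seq.step_minutes
            origin = seq.origin_time + pd.Timedelta(minutes=offset)
        return BehaviorSequence(codes, seq.step_minutes, origin)
    if side == "prefix":
        return BehaviorSequence(
            seq.codes[: n_steps + 1], seq.step_minutes, seq.origin_time
        )
    raise InputError(f"side must be 'suffix' or 'prefix', got {side!r}")
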