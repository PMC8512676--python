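"""End-to-end calving-time prediction and its evaluation.

The prediction pipeline is a deterministic composition:

    sequence -> window -> counts C -> transition matrix P ->
    augmented absorbing chain -> canonical (Q, R) -> N = (I-Q)^-1 ->
    expected calving time (grand sum of N, in minutes) and
    absorption probability p(0) N R.

Evaluation follows the study protocol: each cow's predicted time (hours
from observation start) is compared against a reference actual calving
time — 72 h from the start of observation — and the mean absolute error
is averaged over cows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import absorbing as _absorbing
from . import chain as _chain
from . import counts as _counts
from .core import (
    ABSORBING_LABEL,
    BehaviorSequence,
    InputError,
    TimeWindow,
    window_sequence,
)

__all__ = [
    "PipelineConfig",
    "PredictionResult",
    "EvaluationResult",
    "predict",
    "predict_from_counts",
    "evaluate_mae",
]

DEFAULT_REFERENCE_HOURS = 72.0


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the prediction pipeline.

    ``p0_policy`` chooses the initial distribution for the absorption
    probability: ``'first_state'`` (point mass on the first observed
    state), ``'uniform'`` (over transient states), or an explicit vector
    over the four transient states.
    """

    step_minutes: float = 1.0
    zero_row_policy: str = "error"
    p0_policy: str | Sequence[float] = "first_state"
    reference_hours: float = DEFAULT_REFERENCE_HOURS

    def to_dict(self) -> dict:
        p0 = self.p0_policy
        return {
            "step_minutes": self.step_minutes,
            "zero_row_policy": self.zero_row_policy,
            "p0_policy": p0 if isinstance(p0, str) else list(map(float, p0)),
            "reference_hours": self.reference_hours,
        }


@dataclass(frozen=True)
class PredictionResult:
    """Output of one pipeline run, with full provenance."""

    cow_id: str
    window_hours: float | None
    summary: _absorbing.AbsorptionSummary
    matrices: dict
    config: PipelineConfig

    @property
    def predicted_hours(self) -> float:
        return self.summary.expected_hours

    def to_dict(self) -> dict:
        return {
            "cow_id": self.cow_id,
            "window_hours": self.window_hours,
            "predicted_hours": self.predicted_hours,
            "summary": self.summary.to_dict(),
            "config": self.config.to_dict(),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class EvaluationResult:
    """Per-cow absolute errors and their mean (hours)."""

    per_cow_abs_error: dict[str, float]
    mae: float
    reference_hours: float

    def to_dict(self) -> dict:
        return {
            "reference_hours": self.reference_hours,
            "mae": self.mae,
            "per_cow_abs_error": self.per_cow_abs_error,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                exc.args = (f"[stage {name}] {exc}",) + exc.args[1:]
            return False
    return _Ctx()


def _resolve_p0(
    policy: str | Sequence[float],
    D: _absorbing.AbsorbingDecomposition,
    first_label: str | None,
) -> np.ndarray:
    if isinstance(policy, str):
        if policy == "uniform":
            return np.full(D.m, 1.0 / D.m)
        if policy == "first_state":
            if first_label is None or first_label not in D.transient_order:
                # counts-only input or a sequence starting at calving:
                # fall back to uniform
                return np.full(D.m, 1.0 / D.m)
            p = np.zeros(D.m)
            p[D.transient_order.index(first_label)] = 1.0
            return p
        raise InputError(f"unknown p0_policy {policy!r}")
    p = np.asarray(policy, dtype=float)
    if p.shape != (D.m,):
        raise InputError(f"explicit p0 must have length {D.m}")
    return p


def predict_from_counts(
    C: _counts.CooccurrenceMatrix,
    config: PipelineConfig = PipelineConfig(),
    cow_id: str = "",
    window_hours: float | None = None,
    first_state: str | None = None,
) -> PredictionResult:
    """Run the pipeline from a co-occurrence matrix onward."""
    with _stage("row_normalize"):
        P = _chain.row_normalize(C, zero_row_policy=config.zero_row_policy)
    with _stage("augment_absorbing"):
        P = _chain.augment_absorbing(P)
    with _stage("canonical_decompose"):
        D = _absorbing.canonical_decompose(P)
    with _stage("fundamental_matrix"):
        F = _absorbing.fundamental_matrix(D)
    with _stage("absorption_summary"):
        p0 = _resolve_p0(config.p0_policy, D, first_state)
        summary = _absorbing.absorption_summary(
            F, D, p0, step_minutes=config.step_minutes
        )
    return PredictionResult(
        cow_id=cow_id,
        window_hours=window_hours,
        summary=summary,
        matrices={"C": C, "P": P, "Q": D.Q, "R": D.R, "N": F.N},
        config=config,
    )


def predict(
    seq: BehaviorSequence,
    window: TimeWindow | None = None,
    config: PipelineConfig = PipelineConfig(),
    cow_id: str = "",
) -> PredictionResult:
    """Predict the calving time from a behavior sequence.

    The expected time to calving is the grand sum of the fundamental
    matrix (summed over all four transient start states, the statistic the
    study reports), converted to minutes and hours via the step duration.
    """
    if abs(seq.step_minutes - config.step_minutes) > 1e-9:
        config = PipelineConfig(
            step_minutes=seq.step_minutes,
            zero_row_policy=config.zero_row_policy,
            p0_policy=config.p0_policy,
            reference_hours=config.reference_hours,
        )
    with _stage("window_sequence"):
        if window is not None:
            seq = window_sequence(seq, window)
    with _stage("count_transitions"):
        C = _counts.count_transitions(seq)
    return predict_from_counts(
        C,
        config=config,
        cow_id=cow_id,
        window_hours=None if window is None else window.hours_before_calving,
        first_state=seq.labels[0],
    )


def evaluate_mae(
    predictions: Mapping[str, float] | Sequence[float],
    reference_hours: float = DEFAULT_REFERENCE_HOURS,
) -> EvaluationResult:
    """Mean absolute error of predicted calving times (hours).

    ``predictions`` maps cow ids to predicted hours (or is a plain list,
    in which case 1-based positions are used as ids). The error for each
    cow is |predicted - reference|; the MAE is their arithmetic mean and
    is invariant under reordering of cows.
    """
    if isinstance(predictions, Mapping):
        items = [(str(k), float(v)) for k, v in predictions.items()]
    else:
        items = [(str(i + 1), float(v)) for i, v in enumerate(predictions)]
    if not items:
        raise InputError("evaluate_mae needs at least one prediction")
    errors = {k: abs(v - reference_hours) for k, v in items}
    return EvaluationResult(
        per_cow_abs_error=errors,
        mae=float(np.mean(list(errors.values()))),
        reference_hours=reference_hours,
    )
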