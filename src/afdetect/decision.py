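"""Recording-level aggregation: AF burden and the binary AF call.

A 10-minute recording is compared against a snapshot ECG in a yes/no
fashion: it is called AF when the probable-AF label covers at least 90% of
the classified duration.  Burden is duration-weighted by default (each beat
contributes its own RR interval); warm-up beats are excluded from both
numerator and denominator, so a short warm-up cannot flip the call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import LabeledBeat, RhythmClass, WARMUP_LABEL

__all__ = [
    "IndeterminateRecordingError",
    "RecordingDecision",
    "af_burden",
    "aggregate_recording",
    "to_binary",
    "APP_AF",
    "APP_NO_AF",
]

APP_AF = "app_af"
APP_NO_AF = "app_no_af"


class IndeterminateRecordingError(ValueError):
    """Recording contains no classified (non-warm-up) beats."""


@dataclass(frozen=True)
class RecordingDecision:
    """Binary AF call for one recording.

    ``af_burden`` is the fraction of classified weight (duration by default)
    labeled probable AF; ``call`` is ``"af"`` iff the burden reaches
    ``min_af_fraction``.  ``dominant_non_af_label`` reports the most
    prevalent non-AF class, for display only.
    """

    af_burden: float
    call: str
    dominant_non_af_label: str | None
    classified_duration_ms: float
    warmup_duration_ms: float
    min_af_fraction: float
    weighting: str = "duration"


def _weights(labeled: Sequence[LabeledBeat], weighting: str):
    if weighting not in ("duration", "count"):
        raise ValueError("weighting must be 'duration' or 'count'")
    classified = [b for b in labeled if b.label != WARMUP_LABEL]
    if not classified:
        raise IndeterminateRecordingError(
            "recording has no classified beats (all warm-up)"
        )
    if weighting == "duration":
        w = {b.beat_index: b.rr_ms for b in classified}
    else:
        w = {b.beat_index: 1.0 for b in classified}
    return classified, w


def af_burden(
    labeled: Sequence[LabeledBeat], weighting: str = "duration"
) -> float:
    """Fraction of classified weight labeled probable AF, in [0, 1]."""
    classified, w = _weights(labeled, weighting)
    total = sum(w[b.beat_index] for b in classified)
    af = sum(
        w[b.beat_index]
        for b in classified
        if b.label == RhythmClass.PROBABLE_AF.value
    )
    return af / total


def aggregate_recording(
    labeled: Sequence[LabeledBeat],
    min_af_fraction: float = 0.90,
    weighting: str = "duration",
) -> RecordingDecision:
    """Aggregate per-beat labels into a recording-level AF decision.

    The call is AF iff the burden is at least ``min_af_fraction``
    (inclusive boundary: a burden of exactly 0.90 is AF).
    """
    if not (0 < min_af_fraction <= 1):
        raise ValueError("min_af_fraction must lie in (0, 1]")
    classified, w = _weights(labeled, weighting)
    burden = af_burden(labeled, weighting)

    non_af_weight = {
        RhythmClass.NORMAL.value: 0.0,
        RhythmClass.UNCLASSIFIED_NON_AF.value: 0.0,
    }
    for b in classified:
        if b.label in non_af_weight:
            non_af_weight[b.label] += w[b.beat_index]
    if sum(non_af_weight.values()) > 0:
        # ties break toward NORMAL (dict order), reporting only
        dominant = max(non_af_weight, key=non_af_weight.get)
    else:
        dominant = None

    classified_ms = sum(b.rr_ms for b in classified)
    warmup_ms = sum(b.rr_ms for b in labeled if b.label == WARMUP_LABEL)
    call = "af" if burden >= min_af_fraction else "non_af"
    return RecordingDecision(
        af_burden=burden,
        call=call,
        dominant_non_af_label=dominant,
        classified_duration_ms=classified_ms,
        warmup_duration_ms=warmup_ms,
        min_af_fraction=min_af_fraction,
        weighting=weighting,
    )


def to_binary(decision: RecordingDecision) -> str:
    """Collapse the recording call to the app's binary vocabulary.

    Both non-AF classes (normal rhythm and unclassified non-AF arrhythmia)
    map to the negative app reading.
    """
    return APP_AF if decision.call == "af" else APP_NO_AF
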