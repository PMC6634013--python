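"""Domain types and the streaming per-beat rhythm classifier.

The classifier labels every beat of an RR-interval stream as ``probable_af``,
``normal`` or ``unclassified_non_af`` from a trailing window of the
``window_n`` immediately prior intervals.  Two window features are combined:

* a *variability* index — RMSSD of the window normalised by its mean RR, then
  passed through the saturating map ``v_raw / (v_raw + v_scale)`` so it lives
  in [0, 1];
* a *randomness* index — the first-order conditional Shannon entropy (entropy
  rate) of the ternary symbolisation of successive RR differences
  (decrease / steady / increase around a half-width ``delta_ms``), normalised
  by log 3.

Their weighted sum is the RR-heterogeneity index; two thresholds carve it
into the three rhythm classes.  Atrial fibrillation is both highly variable
and serially unpredictable, so it scores high on both components; atrial
flutter with patterned AV conduction is variable but deterministic at first
order, so its randomness component is exactly zero and it stays out of the
AF class.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "InvalidWindowError",
    "InvalidSeriesError",
    "RhythmClass",
    "WARMUP_LABEL",
    "CLASS_COLORS",
    "RRSeries",
    "ClassifierParams",
    "WindowFeatures",
    "LabeledBeat",
    "variability_index",
    "randomness_index",
    "heterogeneity_index",
    "classify_beat",
    "classify_stream",
]

# Ingestion plausibility bounds for a single RR interval, milliseconds.
DEFAULT_RR_BOUNDS = (240.0, 3000.0)


class InvalidWindowError(ValueError):
    """Window too short or containing non-positive intervals."""


class InvalidSeriesError(ValueError):
    """RR series empty or violating its invariants."""


class RhythmClass(str, enum.Enum):
    """Per-beat rhythm diagnosis."""

    PROBABLE_AF = "probable_af"
    NORMAL = "normal"
    UNCLASSIFIED_NON_AF = "unclassified_non_af"


#: Sentinel label for beats inside the initial warm-up (no full window yet).
WARMUP_LABEL = "warmup"

#: Display colours of the three classes.
CLASS_COLORS = {
    RhythmClass.PROBABLE_AF: "red",
    RhythmClass.NORMAL: "blue",
    RhythmClass.UNCLASSIFIED_NON_AF: "yellow",
}


@dataclass(frozen=True)
class RRSeries:
    """A timestamped beat-to-beat interval sequence.

    Parameters
    ----------
    rr_ms
        Beat-to-beat intervals in milliseconds, strictly positive.
    meta
        Free-form recording annotations (subject id, phase, true rhythm ...).
    flagged
        Boolean mask marking intervals outside the ingestion plausibility
        bounds.  Flagged intervals are kept by default: genuine sensor
        artifacts legitimately raise heterogeneity, mirroring device
        behaviour.
    """

    rr_ms: np.ndarray
    meta: dict = field(default_factory=dict)
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr_ms, dtype=float)
        if rr.ndim != 1 or rr.size < 1:
            raise InvalidSeriesError("RR series must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(rr)) or np.any(rr <= 0):
            raise InvalidSeriesError("all RR intervals must be finite and > 0")
        object.__setattr__(self, "rr_ms", rr)
        if self.flagged is None:
            lo, hi = DEFAULT_RR_BOUNDS
            object.__setattr__(self, "flagged", (rr < lo) | (rr > hi))
        else:
            object.__setattr__(
                self, "flagged", np.asarray(self.flagged, dtype=bool)
            )

    @property
    def t_ms(self) -> np.ndarray:
        """Cumulative beat onset times: ``t[i] = sum(rr[: i + 1])``."""
        return np.cumsum(self.rr_ms)

    @property
    def duration_ms(self) -> float:
        return float(self.rr_ms.sum())

    def __len__(self) -> int:
        return int(self.rr_ms.size)

    def dropped(self) -> "RRSeries":
        """Return a copy with out-of-bounds intervals removed."""
        keep = ~self.flagged
        if not keep.any():
            raise InvalidSeriesError("dropping flagged intervals empties the series")
        return RRSeries(self.rr_ms[keep], dict(self.meta))


@dataclass(frozen=True)
class ClassifierParams:
    """Tunable parameters of the per-beat classifier.

    ``window_n`` immediately prior intervals form the data matrix; ``w_v``
    and ``w_r`` weight the variability and randomness components (must sum
    to 1); ``theta_af``/``theta_sr`` are the upper/lower cutoffs of the
    combined index; ``v_scale`` is the half-saturation constant of the
    variability transform and ``delta_ms`` the symbolisation half-width.
    """

    window_n: int = 32
    w_v: float = 0.5
    w_r: float = 0.5
    theta_af: float = 0.55
    theta_sr: float = 0.25
    v_scale: float = 0.1
    delta_ms: float = 40.0

    def __post_init__(self) -> None:
        if self.window_n < 8:
            raise ValueError("window_n must be >= 8")
        if self.w_v < 0 or self.w_r < 0 or abs(self.w_v + self.w_r - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
        if not (0 <= self.theta_sr < self.theta_af <= 1):
            raise ValueError("require 0 <= theta_sr < theta_af <= 1")
        if self.v_scale <= 0:
            raise ValueError("v_scale must be > 0")
        if self.delta_ms < 0:
            raise ValueError("delta_ms must be >= 0")


@dataclass(frozen=True)
class WindowFeatures:
    """Features of one trailing window."""

    v_raw: float
    v: float
    rn: float
    index: float


@dataclass(frozen=True)
class LabeledBeat:
    """One beat with its diagnosis; ``index_value`` is None during warm-up."""

    beat_index: int
    t_ms: float
    rr_ms: float
    label: str
    index_value: float | None = None


def _check_window(window: np.ndarray, min_len: int) -> np.ndarray:
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < min_len:
        raise InvalidWindowError(f"window needs >= {min_len} intervals, got {w.size}")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise InvalidWindowError("window contains non-positive or non-finite RR")
    return w


def variability_index(window: Sequence[float]) -> float:
    """Normalised RMSSD of one window: RMSSD divided by the mean RR.

    Dimensionless and invariant under a uniform rescaling of the window.
    """
    w = _check_window(window, 2)
    d = np.diff(w)
    rmssd = math.sqrt(float(np.mean(d * d)))
    return rmssd / float(np.mean(w))


def _symbolize(diffs: np.ndarray, delta_ms: float) -> np.ndarray:
    # 0 = decrease, 1 = steady within +-delta, 2 = increase
    return np.where(diffs < -delta_ms, 0, np.where(diffs > delta_ms, 2, 1))


def randomness_index(window: Sequence[float], delta_ms: float = 40.0) -> float:
    """Normalised first-order entropy rate of the ternary ΔRR symbol stream.

    Successive RR differences are symbolised as decrease / steady / increase
    around ``±delta_ms``; the plug-in conditional Shannon entropy of
    symbol pairs, normalised by log 3, is returned.  Exactly zero for any
    deterministic first-order pattern (constant or strictly alternating
    windows), approaching 1 for independent equiprobable symbols.
    """
    w = _check_window(window, 8)
    s = _symbolize(np.diff(w), delta_ms)
    counts = np.zeros((3, 3), dtype=float)
    np.add.at(counts, (s[:-1], s[1:]), 1.0)
    return _conditional_entropy(counts[None, :, :])[0]


def _conditional_entropy(counts: np.ndarray) -> np.ndarray:
    """Normalised H(next | current) from stacked 3x3 pair-count matrices.

    ``counts`` has shape (k, 3, 3); plug-in estimate with 0·log 0 = 0.
    """
    row = counts.sum(axis=2)  # (k, 3)
    total = row.sum(axis=1)  # (k,)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_cond = counts / row[:, :, None]
        plogp = np.where(counts > 0, p_cond * np.log(p_cond), 0.0)
        h_row = -plogp.sum(axis=2)  # (k, 3)
        p_row = np.where(total[:, None] > 0, row / total[:, None], 0.0)
    return (p_row * h_row).sum(axis=1) / math.log(3)


def heterogeneity_index(
    v_raw: float, rn: float, params: ClassifierParams
) -> WindowFeatures:
    """Combine variability and randomness into the RR-heterogeneity index.

    ``v = v_raw / (v_raw + v_scale)`` saturates variability into [0, 1];
    ``index = w_v * v + w_r * rn``.  Monotone nondecreasing in both inputs.
    """
    if v_raw < 0:
        raise ValueError("v_raw must be >= 0")
    if not (0 <= rn <= 1):
        raise ValueError("rn must lie in [0, 1]")
    v = v_raw / (v_raw + params.v_scale)
    index = params.w_v * v + params.w_r * rn
    return WindowFeatures(v_raw=v_raw, v=v, rn=rn, index=index)


def classify_beat(index: float, params: ClassifierParams) -> RhythmClass:
    """Map a heterogeneity index to a rhythm class.

    ``index >= theta_af`` is probable AF; ``index < theta_sr`` is normal;
    the band in between is the unclassified non-AF arrhythmia class.
    """
    if not (0 <= index <= 1):
        raise ValueError("index must lie in [0, 1]")
    if index >= params.theta_af:
        return RhythmClass.PROBABLE_AF
    if index < params.theta_sr:
        return RhythmClass.NORMAL
    return RhythmClass.UNCLASSIFIED_NON_AF


def stream_features(
    rr_ms: np.ndarray, params: ClassifierParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised trailing-window features for every beat.

    Returns arrays ``(v_raw, v, rn, index)`` of length ``len(rr_ms)``; the
    first ``window_n - 1`` entries (warm-up) are NaN.  Identical to calling
    :func:`variability_index` / :func:`randomness_index` on each explicit
    window slice.
    """
    rr = np.asarray(rr_ms, dtype=float)
    n = rr.size
    m = params.window_n
    v_raw = np.full(n, np.nan)
    v = np.full(n, np.nan)
    rn = np.full(n, np.nan)
    idx = np.full(n, np.nan)
    if n < m:
        return v_raw, v, rn, idx

    windows = np.lib.stride_tricks.sliding_window_view(rr, m)  # (k, m)
    d = np.diff(windows, axis=1)  # (k, m - 1)
    rmssd = np.sqrt(np.mean(d * d, axis=1))
    vr = rmssd / windows.mean(axis=1)

    s = _symbolize(d, params.delta_ms)  # (k, m - 1)
    codes = 3 * s[:, :-1] + s[:, 1:]  # (k, m - 2), values 0..8
    counts = np.stack([(codes == c).sum(axis=1) for c in range(9)], axis=1)
    h = _conditional_entropy(counts.reshape(-1, 3, 3).astype(float))

    vv = vr / (vr + params.v_scale)
    v_raw[m - 1 :] = vr
    v[m - 1 :] = vv
    rn[m - 1 :] = h
    idx[m - 1 :] = params.w_v * vv + params.w_r * h
    return v_raw, v, rn, idx


def classify_stream(
    series: RRSeries | Sequence[float] | np.ndarray,
    params: ClassifierParams | None = None,
) -> list[LabeledBeat]:
    """Label every beat of a series from its trailing window.

    Single-pass and causal: the label at beat *i* depends only on beats
    ``<= i``.  The first ``window_n - 1`` beats carry the warm-up sentinel.
    Deterministic: identical inputs give identical labels.
    """
    # The sklearn-style estimator owns the pipeline; this is its functional
    # face (import deferred to avoid a module cycle).
    from .estimators import HeterogeneityBeatClassifier

    if params is None:
        params = ClassifierParams()
    clf = HeterogeneityBeatClassifier(
        window_n=params.window_n,
        w_v=params.w_v,
        w_r=params.w_r,
        theta_af=params.theta_af,
        theta_sr=params.theta_sr,
        v_scale=params.v_scale,
        delta_ms=params.delta_ms,
    )
    return clf.fit().label_series(series)
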