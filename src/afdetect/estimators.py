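"""Scikit-learn-style estimators wrapping the beat and recording classifiers.

Both estimators are stateless rules (nothing is learned from data): ``fit``
validates parameters and marks the estimator fitted, so they compose with
sklearn pipelines, cloning and ``get_params``/``set_params`` as usual.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .core import (
    ClassifierParams,
    InvalidSeriesError,
    LabeledBeat,
    RhythmClass,
    RRSeries,
    WARMUP_LABEL,
    classify_beat,
    stream_features,
)

__all__ = ["HeterogeneityBeatClassifier", "AFRecordingDetector"]


def _as_rr_array(X) -> np.ndarray:
    if isinstance(X, RRSeries):
        return X.rr_ms
    rr = np.asarray(X, dtype=float).ravel()
    if rr.size < 1:
        raise InvalidSeriesError("empty RR series")
    if np.any(rr <= 0) or not np.all(np.isfinite(rr)):
        raise InvalidSeriesError("RR intervals must be finite and > 0")
    return rr


class HeterogeneityBeatClassifier(BaseEstimator):
    """Per-beat three-class rhythm classifier on an RR-interval stream.

    Parameters mirror :class:`afdetect.core.ClassifierParams`.  ``predict``
    returns one label string per beat (``"warmup"`` for the first
    ``window_n - 1``); ``transform`` returns the window features
    ``(v_raw, v, rn, index)`` per beat with NaN rows during warm-up.

    Examples
    --------
    >>> clf = HeterogeneityBeatClassifier().fit()
    >>> labels = clf.predict([800.0] * 40)
    >>> labels[-1]
    'normal'
    """

    def __init__(
        self,
        window_n: int = 32,
        w_v: float = 0.5,
        w_r: float = 0.5,
        theta_af: float = 0.55,
        theta_sr: float = 0.25,
        v_scale: float = 0.1,
        delta_ms: float = 40.0,
    ) -> None:
        self.window_n = window_n
        self.w_v = w_v
        self.w_r = w_r
        self.theta_af = theta_af
        self.theta_sr = theta_sr
        self.v_scale = v_scale
        self.delta_ms = delta_ms

    def fit(self, X=None, y=None) -> "HeterogeneityBeatClassifier":
        """Validate parameters; no statistics are estimated from ``X``."""
        self.params_ = ClassifierParams(
            window_n=self.window_n,
            w_v=self.w_v,
            w_r=self.w_r,
            theta_af=self.theta_af,
            theta_sr=self.theta_sr,
            v_scale=self.v_scale,
            delta_ms=self.delta_ms,
        )
        self.classes_ = np.array([c.value for c in RhythmClass], dtype=object)
        return self

    def transform(self, X) -> np.ndarray:
        """Window features per beat, shape ``(n_beats, 4)``: v_raw, v, rn, index."""
        check_is_fitted(self, "params_")
        rr = _as_rr_array(X)
        return np.column_stack(stream_features(rr, self.params_))

    def decision_index(self, X) -> np.ndarray:
        """The combined heterogeneity index per beat (NaN during warm-up)."""
        return self.transform(X)[:, 3]

    def predict(self, X) -> np.ndarray:
        """One label string per beat."""
        check_is_fitted(self, "params_")
        rr = _as_rr_array(X)
        idx = self.transform(rr)[:, 3]
        p = self.params_
        labels = np.full(rr.size, WARMUP_LABEL, dtype=object)
        classified = ~np.isnan(idx)
        lab = np.full(classified.sum(), RhythmClass.UNCLASSIFIED_NON_AF.value, dtype=object)
        ci = idx[classified]
        lab[ci >= p.theta_af] = RhythmClass.PROBABLE_AF.value
        lab[ci < p.theta_sr] = RhythmClass.NORMAL.value
        labels[classified] = lab
        return labels

    def label_series(self, X) -> list[LabeledBeat]:
        """Full per-beat record: timestamps, RR, label and index value."""
        check_is_fitted(self, "params_")
        rr = _as_rr_array(X)
        idx = self.transform(rr)[:, 3]
        t = np.cumsum(rr)
        out: list[LabeledBeat] = []
        for i in range(rr.size):
            if np.isnan(idx[i]):
                out.append(LabeledBeat(i, float(t[i]), float(rr[i]), WARMUP_LABEL))
            else:
                label = classify_beat(float(idx[i]), self.params_)
                out.append(
                    LabeledBeat(
                        i, float(t[i]), float(rr[i]), label.value, float(idx[i])
                    )
                )
        return out


class AFRecordingDetector(BaseEstimator):
    """Recording-level AF detector: beat labels aggregated into a binary call.

    A recording is called AF when at least ``min_af_fraction`` of its
    classified duration carries the probable-AF label (default 0.90,
    inclusive at the boundary).  ``predict`` maps a sequence of recordings
    (each a 1-D RR array or :class:`RRSeries`) to ``"af"`` / ``"non_af"``.
    """

    def __init__(
        self,
        window_n: int = 32,
        w_v: float = 0.5,
        w_r: float = 0.5,
        theta_af: float = 0.55,
        theta_sr: float = 0.25,
        v_scale: float = 0.1,
        delta_ms: float = 40.0,
        min_af_fraction: float = 0.90,
        weighting: str = "duration",
    ) -> None:
        self.window_n = window_n
        self.w_v = w_v
        self.w_r = w_r
        self.theta_af = theta_af
        self.theta_sr = theta_sr
        self.v_scale = v_scale
        self.delta_ms = delta_ms
        self.min_af_fraction = min_af_fraction
        self.weighting = weighting

    def fit(self, X=None, y=None) -> "AFRecordingDetector":
        if not (0 < self.min_af_fraction <= 1):
            raise ValueError("min_af_fraction must lie in (0, 1]")
        if self.weighting not in ("duration", "count"):
            raise ValueError("weighting must be 'duration' or 'count'")
        self.beat_classifier_ = HeterogeneityBeatClassifier(
            window_n=self.window_n,
            w_v=self.w_v,
            w_r=self.w_r,
            theta_af=self.theta_af,
            theta_sr=self.theta_sr,
            v_scale=self.v_scale,
            delta_ms=self.delta_ms,
        ).fit()
        self.classes_ = np.array(["af", "non_af"], dtype=object)
        return self

    def decide(self, X):
        """Full :class:`afdetect.decision.RecordingDecision` for one recording."""
        check_is_fitted(self, "beat_classifier_")
        from .decision import aggregate_recording

        labeled = self.beat_classifier_.label_series(X)
        return aggregate_recording(
            labeled,
            min_af_fraction=self.min_af_fraction,
            weighting=self.weighting,
        )

    def predict(self, X: Sequence) -> np.ndarray:
        """Binary AF call per recording in ``X`` (a sequence of recordings)."""
        return np.array([self.decide(rec).call for rec in X], dtype=object)
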