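"""Readers and writers for RR-series files and result JSON documents.

The RR text format is a plain CSV with header ``beat_index,t_ms,rr_ms`` —
one row per beat, milliseconds throughout.  ``write_rr`` then ``read_rr``
is the identity on any valid series; malformed rows are reported with their
line number.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import ClassifierParams, LabeledBeat, RRSeries
from .decision import RecordingDecision

__all__ = [
    "RRParseError",
    "read_rr",
    "write_rr",
    "labeled_to_json",
    "decision_to_json",
    "write_json",
    "read_manifest",
    "write_manifest",
]

RR_HEADER = ["beat_index", "t_ms", "rr_ms"]


class RRParseError(ValueError):
    """Malformed RR file; the message names the offending line."""


def write_rr(series: RRSeries, path: str | Path) -> None:
    """Write a series to the CSV beat format."""
    t = series.t_ms
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RR_HEADER)
        for i, (ti, rri) in enumerate(zip(t, series.rr_ms)):
            w.writerow([i, f"{ti:.6g}", f"{rri:.6g}"])


def read_rr(path: str | Path, meta: dict | None = None) -> RRSeries:
    """Read a series from the CSV beat format, validating every row."""
    rr: list[float] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RRParseError(f"{path}: empty file") from None
        if [h.strip() for h in header] != RR_HEADER:
            raise RRParseError(
                f"{path}: line 1: expected header {','.join(RR_HEADER)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise RRParseError(f"{path}: line {lineno}: expected 3 columns")
            try:
                val = float(row[2])
            except ValueError:
                raise RRParseError(
                    f"{path}: line {lineno}: non-numeric rr_ms {row[2]!r}"
                ) from None
            if val <= 0:
                raise RRParseError(f"{path}: line {lineno}: non-positive rr_ms {val}")
            rr.append(val)
    if not rr:
        raise RRParseError(f"{path}: no beats (header-only file)")
    return RRSeries(np.asarray(rr), meta=dict(meta or {}))


def labeled_to_json(
    labeled: Sequence[LabeledBeat],
    params: ClassifierParams,
    meta: dict | None = None,
) -> dict:
    """JSON document for a labeled recording, embedding the resolved params."""
    return {
        "meta": dict(meta or {}),
        "params": asdict(params),
        "beats": [
            {
                "beat_index": b.beat_index,
                "t_ms": b.t_ms,
                "rr_ms": b.rr_ms,
                "label": b.label,
                "index_value": b.index_value,
            }
            for b in labeled
        ],
    }


def decision_to_json(decision: RecordingDecision, meta: dict | None = None) -> dict:
    return {
        "meta": dict(meta or {}),
        "af_burden": decision.af_burden,
        "call": decision.call,
        "dominant_non_af_label": decision.dominant_non_af_label,
        "min_af_fraction": decision.min_af_fraction,
        "weighting": decision.weighting,
        "classified_duration_ms": decision.classified_duration_ms,
        "warmup_duration_ms": decision.warmup_duration_ms,
    }


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_manifest(recordings, path: str | Path, spec_echo: dict | None = None) -> None:
    """Manifest JSON for a simulated study corpus: truth labels and seeds."""
    doc = {
        "spec": dict(spec_echo or {}),
        "recordings": [
            {
                "recording_id": r.recording_id,
                "patient_id": r.patient_id,
                "phase": r.phase,
                "truth": r.truth,
                "seed": r.seed,
                "file": f"{r.recording_id}.rr.csv",
            }
            for r in recordings
        ],
    }
    write_json(doc, path)


def read_manifest(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if "recordings" not in doc:
        raise ValueError(f"{path}: not a corpus manifest (no 'recordings' key)")
    return doc
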