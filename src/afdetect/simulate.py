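"""Seeded synthetic RR-interval generators and a cardioversion-study emulator.

No public RR recordings accompany the validation study this package models,
so every rhythm class the detector must discriminate is synthesised:

* sinus rhythm (SR) — small respiratory modulation of the RR interval plus
  Gaussian beat-to-beat noise;
* atrial fibrillation (AF) — an "irregularly irregular" ventricular
  response: i.i.d. Gamma RR intervals with no serial correlation;
* atrial flutter (AFL) — a "regularly irregular" response: a fixed atrial
  cycle length conducted at a fixed or deterministically repeating AV
  ratio, with small jitter;
* ectopic beats (PAC/PVC-like) and sensor artifacts (missed or split beat
  detections) layered on any base rhythm.

``simulate_study`` reproduces the enrollment structure of a paired
pre-/post-cardioversion accuracy study: 100 enrolled, 5 excluded for
spontaneous conversion, 87 AF + 8 flutter at the procedure, 83 successful
cardioversions, 4 of them with very frequent post-procedural ectopy.
Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .core import RRSeries

__all__ = [
    "RhythmSpec",
    "StudySpec",
    "StudyRecording",
    "simulate_sr",
    "simulate_af",
    "simulate_aflutter",
    "inject_ectopy",
    "inject_artifacts",
    "simulate_study",
]


@dataclass(frozen=True)
class RhythmSpec:
    """Parameters of one synthetic recording.

    Rhythm-specific fields: SR uses ``resp_freq_hz``/``resp_amp``/``sigma_ms``;
    AF uses ``cv`` (coefficient of variation of the Gamma RR distribution);
    AFL uses ``cycle_ms`` (atrial cycle length), ``conduction`` (fixed k:1 or
    a repeating ratio pattern) and ``jitter_ms``.
    """

    rhythm: Literal["sr", "af", "aflutter"] = "sr"
    duration_s: float = 600.0
    mean_rr_ms: float = 800.0
    seed: int = 0
    # SR
    resp_freq_hz: float = 0.25
    resp_amp: float = 0.03
    sigma_ms: float = 15.0
    # AF
    cv: float = 0.20
    af_bounds_ms: tuple[float, float] = (300.0, 1800.0)
    # AFL
    cycle_ms: float = 220.0
    conduction: tuple[int, ...] = (2, 4)
    jitter_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.mean_rr_ms <= 0:
            raise ValueError("mean_rr_ms must be > 0")


@dataclass(frozen=True)
class StudySpec:
    """Enrollment and outcome counts of the emulated cardioversion study."""

    n_enrolled: int = 100
    n_spontaneous_conversion: int = 5
    n_aflutter: int = 8
    n_success: int = 83
    n_post_ecv_ectopy: int = 4
    ectopy_rate: float = 0.18
    seed: int = 0
    duration_s: float = 600.0

    @property
    def n_included(self) -> int:
        return self.n_enrolled - self.n_spontaneous_conversion

    @property
    def n_af(self) -> int:
        return self.n_included - self.n_aflutter

    def __post_init__(self) -> None:
        if self.n_spontaneous_conversion >= self.n_enrolled:
            raise ValueError("spontaneous conversions must leave included patients")
        if self.n_aflutter > self.n_included or self.n_success > self.n_included:
            raise ValueError("subgroup counts exceed included patients")
        # flutter patients all convert, so failures must fit inside the AF group
        if self.n_included - self.n_success > self.n_af:
            raise ValueError("more ECV failures than AF patients")
        if self.n_post_ecv_ectopy > self.n_success:
            raise ValueError("ectopy count exceeds successful conversions")


@dataclass(frozen=True)
class StudyRecording:
    """One recording of the emulated corpus with its ground truth."""

    recording_id: str
    patient_id: int
    phase: Literal["pre", "post"]
    truth: Literal["af", "aflutter", "sr"]
    seed: int
    series: RRSeries


def _truncate_to_duration(rr: np.ndarray, duration_ms: float) -> np.ndarray:
    """Keep beats up to and including the first whose onset reaches duration."""
    t = np.cumsum(rr)
    stop = np.searchsorted(t, duration_ms, side="left")
    return rr[: min(stop + 1, rr.size)]


def simulate_sr(spec: RhythmSpec) -> RRSeries:
    """Sinus rhythm: respiratory sinusoidal modulation plus Gaussian noise.

    ``rr_i = mu * (1 + a * sin(2 pi f t_{i-1})) + sigma * eps_i`` with the
    phase driven by the accumulated beat time, so the modulation tracks real
    respiratory cycles rather than beat count.
    """
    rng = np.random.default_rng(spec.seed)
    mu, a, f, sigma = spec.mean_rr_ms, spec.resp_amp, spec.resp_freq_hz, spec.sigma_ms
    duration_ms = spec.duration_s * 1000.0
    n_max = int(duration_ms / mu * 1.5) + 8
    eps = rng.standard_normal(n_max)
    rr = np.empty(n_max)
    t = 0.0
    n = 0
    for i in range(n_max):
        val = mu * (1.0 + a * math.sin(2 * math.pi * f * t / 1000.0)) + sigma * eps[i]
        val = max(val, 1.0)  # guard: noise cannot produce a non-positive beat
        rr[i] = val
        t += val
        n = i + 1
        if t >= duration_ms:
            break
    return RRSeries(rr[:n], meta={"rhythm": "sr", "seed": spec.seed})


def simulate_af(spec: RhythmSpec) -> RRSeries:
    """Atrial fibrillation: i.i.d. Gamma RR intervals, no serial correlation.

    Mean ``mean_rr_ms`` and coefficient of variation ``cv``; samples outside
    ``af_bounds_ms`` are rejected and redrawn so the ventricular response
    stays physiological.
    """
    rng = np.random.default_rng(spec.seed)
    mu, c = spec.mean_rr_ms, spec.cv
    duration_ms = spec.duration_s * 1000.0
    lo, hi = spec.af_bounds_ms
    if c <= 0:
        n = int(math.ceil(duration_ms / mu))
        return RRSeries(np.full(n, mu), meta={"rhythm": "af", "seed": spec.seed})
    shape = 1.0 / (c * c)
    scale = mu * c * c
    chunks: list[np.ndarray] = []
    total = 0.0
    while total < duration_ms:
        x = rng.gamma(shape, scale, size=256)
        x = x[(x >= lo) & (x <= hi)]
        chunks.append(x)
        total += float(x.sum())
    rr = _truncate_to_duration(np.concatenate(chunks), duration_ms)
    return RRSeries(rr, meta={"rhythm": "af", "seed": spec.seed})


def simulate_aflutter(spec: RhythmSpec) -> RRSeries:
    """Atrial flutter: patterned AV conduction of a fixed atrial cycle.

    Each RR equals ``k * cycle_ms`` for ``k`` cycling through the
    ``conduction`` pattern (e.g. ``(2,)`` for fixed 2:1, ``(2, 4)`` for
    alternating 2:1/4:1), plus Gaussian jitter.  With zero jitter and a
    fixed ratio the series is exactly constant.
    """
    rng = np.random.default_rng(spec.seed)
    duration_ms = spec.duration_s * 1000.0
    pattern = np.asarray(spec.conduction, dtype=float)
    if pattern.size < 1 or np.any(pattern < 1):
        raise ValueError("conduction pattern must hold ratios >= 1")
    base_mean = float(pattern.mean()) * spec.cycle_ms
    n_max = int(duration_ms / base_mean * 1.5) + 8
    ks = np.resize(pattern, n_max)
    rr = ks * spec.cycle_ms + spec.jitter_ms * rng.standard_normal(n_max)
    rr = np.maximum(rr, 1.0)
    rr = _truncate_to_duration(rr, duration_ms)
    return RRSeries(rr, meta={"rhythm": "aflutter", "seed": spec.seed})


def inject_ectopy(
    series: RRSeries,
    rate_per_beat: float,
    coupling_fraction: float = 0.7,
    compensatory: bool = False,
    seed: int = 0,
) -> RRSeries:
    """Insert premature beats into a series.

    At each original beat, with probability ``rate_per_beat``, the interval
    ``rr`` is replaced by the pair ``(coupling_fraction * rr, remainder)``.
    In compensatory (interpolated PVC-like) mode the remainder completes the
    underlying cycle (``remainder = (1 - coupling_fraction) * rr``), so the
    total duration is conserved to the millisecond; in non-compensatory
    (PAC-like) mode the pacemaker resets and the post-ectopic interval is a
    full underlying cycle (``remainder = rr``).  Either way the beat count
    grows by one per ectopic.
    """
    if not (0 <= rate_per_beat <= 0.5):
        raise ValueError("rate_per_beat must lie in [0, 0.5]")
    if not (0 < coupling_fraction < 1):
        raise ValueError("coupling_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    hits = rng.random(len(series)) < rate_per_beat
    out: list[float] = []
    for rr, hit in zip(series.rr_ms, hits):
        if hit:
            coupled = coupling_fraction * rr
            remainder = (rr - coupled) if compensatory else rr
            out.extend((coupled, remainder))
        else:
            out.append(rr)
    meta = dict(series.meta)
    meta["ectopy_rate"] = rate_per_beat
    return RRSeries(np.asarray(out), meta=meta)


def inject_artifacts(
    series: RRSeries,
    drop_prob: float = 0.0,
    split_prob: float = 0.0,
    seed: int = 0,
) -> RRSeries:
    """Sensor imperfections: missed detections merge two adjacent intervals
    into their sum, split detections divide one interval into two halves.
    Total duration is conserved exactly.
    """
    for p in (drop_prob, split_prob):
        if not (0 <= p <= 0.2):
            raise ValueError("artifact probabilities must lie in [0, 0.2]")
    rng = np.random.default_rng(seed)
    rr = list(series.rr_ms)
    out: list[float] = []
    i = 0
    while i < len(rr):
        u = rng.random()
        if u < drop_prob and i + 1 < len(rr):
            out.append(rr[i] + rr[i + 1])
            i += 2
        elif u < drop_prob + split_prob:
            out.extend((rr[i] / 2.0, rr[i] / 2.0))
            i += 1
        else:
            out.append(rr[i])
            i += 1
    meta = dict(series.meta)
    meta["artifacts"] = {"drop_prob": drop_prob, "split_prob": split_prob}
    return RRSeries(np.asarray(out), meta=meta)


def _rhythm_series(rhythm: str, seed: int, duration_s: float) -> RRSeries:
    spec = RhythmSpec(rhythm=rhythm, duration_s=duration_s, seed=seed)  # type: ignore[arg-type]
    if rhythm == "sr":
        return simulate_sr(replace(spec, mean_rr_ms=800.0))
    if rhythm == "af":
        return simulate_af(replace(spec, mean_rr_ms=600.0))
    if rhythm == "aflutter":
        # half the synthetic flutter patients conduct at a fixed ratio,
        # half alternate, covering both "regularly irregular" shapes
        conduction = (2,) if seed % 2 == 0 else (2, 4)
        return simulate_aflutter(replace(spec, conduction=conduction))
    raise ValueError(f"unknown rhythm {rhythm!r}")


def simulate_study(spec: StudySpec | None = None) -> list[StudyRecording]:
    """Emulate the paired pre-/post-cardioversion corpus.

    With defaults: 95 included patients (100 enrolled minus 5 spontaneous
    conversions), hence 190 recordings; pre-procedure truths are 87 AF and
    8 flutter; all flutter patients convert, 12 AF patients fail, giving 83
    post-procedure sinus-rhythm recordings of which 4 carry very frequent
    non-compensatory ectopy.  Counts are deterministic; per-recording seeds
    are spawned from ``spec.seed``.
    """
    if spec is None:
        spec = StudySpec()
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * spec.n_included + spec.n_included)]
    seed_iter = iter(child_seeds)

    n_failures = spec.n_included - spec.n_success
    recordings: list[StudyRecording] = []
    n_ectopy_assigned = 0
    for p in range(1, spec.n_included + 1):
        pre_truth = "af" if p <= spec.n_af else "aflutter"
        # ECV fails only in the AF group; the last n_failures AF patients fail
        failed = pre_truth == "af" and p > spec.n_af - n_failures
        post_truth = pre_truth if failed else "sr"

        pre_seed = next(seed_iter)
        post_seed = next(seed_iter)
        ect_seed = next(seed_iter)

        pre = _rhythm_series(pre_truth, pre_seed, spec.duration_s)
        post = _rhythm_series(post_truth, post_seed, spec.duration_s)
        if post_truth == "sr" and n_ectopy_assigned < spec.n_post_ecv_ectopy:
            post = inject_ectopy(
                post, spec.ectopy_rate, compensatory=False, seed=ect_seed
            )
            n_ectopy_assigned += 1

        for phase, truth, series, seed in (
            ("pre", pre_truth, pre, pre_seed),
            ("post", post_truth, post, post_seed),
        ):
            series.meta.update(
                {"patient_id": p, "phase": phase, "truth": truth}
            )
            recordings.append(
                StudyRecording(
                    recording_id=f"p{p:03d}_{phase}",
                    patient_id=p,
                    phase=phase,  # type: ignore[arg-type]
                    truth=truth,  # type: ignore[arg-type]
                    seed=seed,
                    series=series,
                )
            )
    return recordings
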