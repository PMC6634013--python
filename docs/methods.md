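# Methods

## The detection problem

A chest-strap heart-rate monitor delivers a stream of RR intervals
(milliseconds between consecutive ventricular beats) and nothing else — no
ECG waveform, no atrial activity. Atrial fibrillation (AF) must therefore
be recognised purely from the statistics of the RR sequence. Two properties
separate the rhythms of interest:

* **AF** is *irregularly irregular*: large beat-to-beat variability **and**
  no serial predictability.
* **Sinus rhythm (SR)** has small variability dominated by smooth
  respiratory modulation.
* **Atrial flutter (AFL)** and similar re-entrant tachycardias are
  *regularly irregular*: RR intervals may jump between discrete values
  (AV conduction ratios of a fixed atrial cycle) but do so in a
  deterministic or near-deterministic pattern.

A variability measure alone confuses AFL (and frequent ectopy) with AF; a
randomness measure alone is insensitive to rate. The detector combines
both.

## Per-beat index

For each beat `i ≥ n − 1`, the window `w = (rr[i−n+1], …, rr[i])` of the
`n = 32` immediately prior intervals gives:

* **Variability** `v_raw = RMSSD(w) / mean(w)` — the root mean square of
  successive differences normalised by the window mean, so the index is
  dimensionless and invariant under uniform time rescaling. The saturating
  map `v = v_raw / (v_raw + c)` with `c = 0.1` compresses it into [0, 1];
  `c` equals the typical normalised RMSSD halfway between SR (~0.04) and AF
  (~0.28), so the transform is steepest where the rhythms separate.
* **Randomness** `r`: successive differences `Δrr` are symbolised as
  decrease (`Δ < −δ`), steady (`|Δ| ≤ δ`) or increase (`Δ > +δ`), and `r`
  is the plug-in conditional Shannon entropy of symbol pairs
  (`H(next | current)`, with `0·log 0 = 0`), normalised by `log 3`. Any
  first-order-deterministic pattern — constant series, strict alternation
  such as 2:1/4:1 flutter conduction — scores exactly 0; i.i.d.
  equiprobable symbols approach 1. No bias correction is applied: the
  window is short and the value is a bounded feature, not an estimator of a
  population entropy.
* **Combination** `H = w_v·v + w_r·r` with `w_v = w_r = 0.5`, monotone in
  both components and confined to [0, 1].

Thresholds `θ_AF = 0.55` (inclusive) and `θ_SR = 0.25` split `H` into
probable AF / unclassified non-AF / normal. The first `n − 1` beats carry a
warm-up sentinel and are excluded from all aggregation.

The exact index of the commercial system this design follows is
proprietary and unpublished; the formulas above are this package's own
declared realisation of a "weighted combination of RR variability and
randomness", not a reconstruction of any vendor's coefficients.

## Parameter defaults and calibration

| parameter | default | units | rationale |
|---|---|---|---|
| `window_n` | 32 | beats | ~20–30 s latency at rest; ≥ 30 symbol pairs for the entropy estimate |
| `w_v`, `w_r` | 0.5 / 0.5 | — | equal weight to the two halves of the AF signature |
| `θ_AF`, `θ_SR` | 0.55 / 0.25 | — | AF requires support from both components (`H > w_v` is unreachable with `r = 0`); SR band below the unclassified band |
| `v_scale` | 0.1 | — | half-saturation at the SR/AF midpoint of normalised RMSSD |
| `δ` (`delta_ms`) | 40 | ms | see below |
| `min_af_fraction` | 0.90 | — | the burden rule: AF call iff ≥ 90% of classified duration is probable AF, boundary inclusive |

The defaults were calibrated **once** against the synthetic corpora and
then frozen. The symbolisation half-width δ is the one value the
calibration moved: at δ = 25 ms nearly every AF difference (std ≈ 170 ms)
exceeds the band, collapsing AF onto two symbols whose successive signs are
anti-correlated (adjacent differences share a beat), which caps AF's
conditional entropy *below* sinus rhythm's three-symbol mix — inverting the
intended ordering on long windows. δ = 40 ms restores the ordering
(AF > SR entropy on 100/100 seeded pairs) while keeping every
recording-level contract (AF sensitivity and SR specificity 100/100 at ten
minutes, flutter 0/8, ectopy-driven false calls strictly increasing in
ectopy rate); δ = 50 ms over-smooths ectopic coupling intervals and
suppresses the false-positive mechanism entirely. δ is an absolute
millisecond width by design — scale invariance of the full classifier holds
when δ is rescaled together with the data, and the variability component is
scale-invariant on its own.

## Recording-level decision

AF burden = Σ rr over probable-AF beats ÷ Σ rr over all classified beats
(duration weighting; a `count` mode is available and nearly identical for
stationary 10-minute recordings). The binary call is AF iff burden ≥ 0.90,
"at least" read inclusively. Both non-AF classes collapse to the negative
reading for accuracy analysis. Warm-up exclusion from numerator *and*
denominator keeps short fixtures well defined and cannot flip a
10-minute recording (warm-up is ~3% of its duration).

## Synthetic data: what it emulates and what it does not

* **SR**: `rr_i = μ(1 + a·sin 2πf·t_{i−1}) + σ·ε_i`, μ = 800 ms, a = 0.03,
  f = 0.25 Hz, σ = 15 ms — literature-typical resting values (CV ≈ 0.04,
  positive lag-1 autocorrelation from the respiratory term). The phase is
  driven by accumulated time, not beat count.
* **AF**: i.i.d. Gamma intervals, μ = 600 ms, CV = 0.20, rejection-truncated
  to [300, 1800] ms (the plausible ventricular response range in untreated
  AF); zero serial correlation by construction.
* **AFL**: atrial cycle 220 ms conducted at a fixed ratio (2:1 → constant
  440 ms) or an alternating 2:1/4:1 pattern (440/880 ms), jitter σ = 5 ms.
* **Ectopy**: with probability `rate` per beat, `rr` becomes
  `(0.7·rr, remainder)`; compensatory (interpolated-PVC-like) mode
  completes the cycle (`remainder = 0.3·rr`, duration conserved exactly),
  non-compensatory (PAC-like) mode resets the pacemaker
  (`remainder = rr`). Both add one beat per ectopic.
* **Artifacts**: missed detections merge adjacent intervals, split
  detections halve one; duration is conserved exactly.
* **Study emulation**: deterministic counts — 100 enrolled, 5 spontaneous
  conversions excluded, 95 patients × 2 recordings = 190; 87 AF + 8 AFL
  before cardioversion; all flutter patients and 75 AF patients convert
  (83 successes), 12 AF patients fail; the first 4 converted patients carry
  frequent non-compensatory ectopy (rate 0.18/beat), the documented
  post-cardioversion false-positive mechanism. Per-recording seeds are
  spawned from the study seed.

These generators reproduce the *qualitative* structure the detector relies
on — they are not patient data. They omit rate drift, autonomic transients,
paroxysmal onsets/offsets, rate-control drugs and realistic sensor noise
spectra. Passing the synthetic calibration therefore shows the
implementation realises the intended decision geometry (AF high/high, SR
low/low, AFL variable/deterministic, ectopy as the false-positive channel);
it does **not** certify clinical accuracy. The clinical headline numbers in
this repository come only from replaying the published contingency counts,
which is an exact, deterministic computation.

## Accuracy statistics

Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) carry Clopper–Pearson
intervals by default (statsmodels' beta inversion; Wilson optional).
Flutter is handled both ways — excluded (the three-category reading of the
study) and as a true negative (the binary reading); sensitivity is
provably identical under both. Cohen's κ = (p_o − p_e)/(1 − p_e) is
computed on the binary collapse with the large-sample standard-error
interval `SE = sqrt(p_o(1−p_o)/n)/(1−p_e)`; a bootstrap is deliberately
out of scope. Which CI procedure produced the originally printed intervals
is unknown, so CI bounds are reported but never asserted against.

## Numerical choices and degenerate inputs

* Streaming features are computed vectorised over all trailing windows and
  are bit-identical to brute-force recomputation on explicit window slices
  (tested over 1000 windows).
* Boundary conventions: `H ≥ θ_AF` is AF; `H < θ_SR` is normal; ties at
  `θ_SR` fall in the middle band. Burden exactly 0.90 is an AF call.
* Ingestion accepts RR in [240, 3000] ms; out-of-range intervals are
  flagged and kept (a `dropped()` view removes them) — artifacts
  legitimately raise heterogeneity, which is part of the detector's
  behaviour.
* A recording whose every beat is warm-up raises an indeterminate-recording
  error rather than returning a call; empty series, non-positive intervals
  and malformed files are rejected with located error messages.
* Dominant-non-AF reporting breaks ties toward `normal`.

## Known limitations

* Per-beat SR labels concentrate in the unclassified band rather than the
  normal band (the SR index sits near 0.45 under default weights): the
  recording-level call is unaffected, but per-beat colour maps of clean SR
  look more cautious than a tuned commercial display would.
* The entropy estimate at window 32 rests on 30 symbol pairs; its downward
  plug-in bias is part of the calibrated operating point rather than
  corrected.
* Thresholds were calibrated on the synthetic corpora only; transferring
  them to real sensor data would require re-calibration against annotated
  recordings.
* The binary burden rule cannot represent recordings with intermediate
  (10–90%) AF labelling; by the stated rule they are negative calls.
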