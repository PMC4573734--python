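# Methods

## Model and assumptions

The detector assumes that AF manifests in the RR series as a wide,
near-memoryless occupancy of instantaneous heart-rate states, while
non-AF rhythms (sinus rhythm above all) occupy a narrow, slowly drifting
band. It quantifies this with the entropy of 3-symbol words over a
sliding window:

- Heart rate `hr = 60000 / rr_ms` is kept real-valued; the single floor
  happens inside the symbol map `sy = 63 if hr ≥ 315 else ⌊hr/5⌋`.
  Heart rates exactly on a 5-bpm bin edge follow IEEE floor semantics
  (65.0 bpm → symbol 13); no epsilon nudging is applied.
- Words pack three consecutive symbols by 6-bit shifts, a bijection onto
  a subset of [0, 262143]; the word stream is two beats shorter than the
  beat stream.
- The coarse Shannon entropy over the last N = 127 words is
  `H″ = −(k/(N log₂N)) Σ pᵢ log₂ pᵢ` with `pᵢ = Nᵢ/N`. The probability
  denominator is the *nominal* N even while the window is filling —
  that is what the count-indexed lookup recursion computes, and the
  floating-point oracle mirrors it so both routes agree from the first
  word.
- A beat is AF iff `H″ ≥ threshold`; the tie goes to AF ("meets or
  exceeds"). The comparison uses full float precision.

The method consumes beat sequences only: QRS detection, waveform
filtering and ectopic-beat handling are out of scope.

## Streaming engine

`EntropyState.push` performs the slide-out/slide-in update: remove the
oldest word's lookup term at its old count, decrement, re-add at the new
count, decrement k if the count reached zero; mirror for the incoming
word; then `H″ = k·acc/(N·Cons)`. The lookup table holds
`⌊(Cons/log₂N)(−pᵢ log₂ pᵢ)⌋` for counts 0..N with `PiMap[0] = 0` by
convention and `Cons = 10⁶`. Every push is O(1): a constant number of
integer adds/subtracts/compares plus one multiply and one divide.

Numerical notes:

- The accumulator is an exact Python integer; it is bounded by
  `N · max(PiMap) = 127 · 75941 < 10⁷`, far inside any fixed-width
  integer a port would use (the update logic needs ≥ 32 bits).
- Table quantisation: each entry carries a floor error < 1, at most k ≤ N
  terms contribute, and the sum is scaled by `k/(N·Cons)`, so
  `|H″(recursive) − H″(direct)| ≤ k²/(N·Cons) < 1.3e−4`. The test suite
  asserts 2e−4 over seeded random streams.
- Word counts live in a plain dict keyed by word value. A dense array of
  262144 counters is the natural choice on embedded targets; in Python
  the dict costs the same O(1) amortised access and keeps state size
  proportional to the window, not the alphabet.

## Detector state contract

All state is zeroed per record; records never share a window. The first
defined decision is at beat index 128 (0-based): two beats form the
first word, 126 more fill the window. Earlier beats are warm-up, and
`warmup_policy` selects their treatment: `mark` (default) labels them
WARMUP and the evaluator skips them — under-filled windows would
otherwise bias the metrics; `nonaf` forces NONAF for consumers that need
a binary stream; `drop` omits them. Decisions are attached to the
current beat (causal labelling), not centre-shifted; the effective
detection latency is about half a window (~65 beats) and shows up as
misclassifications at rhythm transitions, not as an output shift.

## Evaluation

Beat-level Se/Sp/PPV/ACC with AF positive. A metric with a zero
denominator is undefined (None), never 0. PPV is additionally
not-applicable when the reference contains no AF beat, matching the
screening convention for AF-free databases. The ROC sweep tests
thresholds 0.0–1.0 in 0.001 steps, integrates AUC trapezoidally over
(1−Sp, Se) with (0,0)/(1,1) endpoints appended when the sweep does not
reach them, and picks the operating point with the smallest Euclidean
distance to (0, 1), breaking ties toward the smallest threshold.
Interval rhythm annotations expand to per-beat labels with half-open
`[onset, next-onset)` semantics; only `(AFIB` maps to AF by default —
atrial flutter `(AFL` is non-AF unless the caller adds it to
`af_codes`.

## Synthetic data

The generator emulates the statistical contrast the detector exploits,
not cardiac physiology:

- **NSR**: `hr_i = 70 + 3·sin(2πi/60) + N(0, 2²)` bpm — a slow
  respiratory-like modulation (±3 bpm over 60 beats) plus small
  beat-to-beat jitter (SD 2 bpm), chosen to span only ~3–4 of the 5-bpm
  symbol bins, as resting sinus rhythm does. A sinusoid-plus-noise model
  was preferred over an AR(1) for analytic transparency.
- **AF**: RR i.i.d. uniform on [300, 1000] ms (60–200 bpm, ~28 symbol
  bins) — the simplest model of AF's near-memoryless irregularity.
- **Paroxysmal**: labelled concatenation of such segments; one seeded
  RNG drives everything, so a config reproduces its record bit-for-bit.

What passing tests on these data do show: the full pipeline separates
wide-memoryless from narrow-drifting rhythm at the default threshold,
causally and deterministically. What they do not show: performance on
real ECG-derived beats, where ectopy, sensing artefacts, flutter and
rate-controlled AF blur the separation; clinical-grade figures require
the optional database workflow. Segment-level recovery tests exclude one
window width (130 beats) around each rhythm switch, where the window
necessarily mixes rhythms.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `N` | 127 | entropy window, words (~2 min at 70 bpm); small windows estimate the word distribution poorly |
| `Cons` | 10⁶ | integer scale of the lookup table |
| `threshold` | 0.639 | decision level on H″, from ROC training on a long-term AF database |
| `hr_cap` / `bin_width` | 315 / 5 bpm | 64-symbol alphabet |
| NSR mean/SD/drift | 70 / 2 / ±3 bpm | resting sinus band |
| AF RR range | 300–1000 ms | 60–200 bpm ventricular response |

## Known limitations

- Per-beat classification only; no episode-level smoothing or minimum
  duration rules, so isolated flips near the threshold pass through.
- Very short AF episodes (≲ window length) are attenuated by the
  127-word window and may be missed.
- Rhythms that mimic AF's state occupancy (e.g. very irregular ectopy)
  raise H″ and cause false positives; the method does not filter
  ectopic beats.
- The binary WFDB formats are not parsed; annotations must be exported
  to text (rdann-style) first.
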