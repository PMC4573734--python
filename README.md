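# afdetect

Real-time, beat-by-beat screening for **atrial fibrillation (AF)** from
RR-interval (heart-rate) streams, using symbolic dynamics and a
recursively updated coarse Shannon entropy.

AF produces a chaotic ventricular response: successive RR intervals are
highly irregular and nearly memoryless, while sinus rhythm drifts slowly
within a narrow band. `afdetect` turns this contrast into a per-beat
classifier cheap enough for wearable/embedded use — each beat costs a
handful of integer operations, one multiply and one divide.

## Method

For each beat *n* with RR interval `rr_n` (ms):

1. **Symbolisation.** Instantaneous heart rate `hr_n = 60000 / rr_n`
   (bpm) is quantised into one of 64 states:
   `sy_n = 63` if `hr_n ≥ 315`, else `⌊hr_n / 5⌋`.
2. **Word encoding.** Three consecutive symbols form a word
   `wv_n = (sy_{n−2} << 12) | (sy_{n−1} << 6) | sy_n ∈ [0, 262143]`,
   e.g. symbols `0,1,3 → 67`.
3. **Coarse Shannon entropy.** Over the window **A** of the last
   N = 127 words with k distinct values and counts `N_i`,

   ```
   H″(A) = −(k / (N log₂N)) Σᵢ pᵢ log₂ pᵢ,   pᵢ = Nᵢ / N ∈ (0, 1]
   ```

   so `H″ ∈ [0, 1]`: 0 when one word fills the window, 1 when all 127
   differ.
4. **Decision.** Beat *n* is labelled AF iff `H″ ≥ threshold`
   (default 0.639, selected by ROC analysis on a long-term training
   database). The first 128 beats of a record are warm-up.

The streaming engine never evaluates a logarithm: the per-count terms
`⌊(Cons/log₂N) · (−pᵢ log₂ pᵢ)⌋` (Cons = 10⁶) are precomputed into an
integer lookup table (`PiMap`, entries `0, 7874, …, 71790, 71291, …, 0`),
and each beat's update slides one word out and one in with O(1) integer
adds/subtracts, then forms `H″ = k · acc / (N · Cons)`.

The package also provides the evaluation machinery (beat-level
Se/Sp/PPV/ACC, ROC sweep with trapezoidal AUC and closest-to-ideal
threshold selection), rdann-style rhythm-annotation expansion, and a
seeded synthetic RR generator (sinus rhythm / AF / paroxysmal switching)
so the whole pipeline is testable without any database download.

## Worked example

```python
import numpy as np
from afdetect import (SimConfig, gen_paroxysmal, detect_stream,
                      confusion, metrics, roc_sweep, WARMUP)

stream = gen_paroxysmal(SimConfig(seed=42,
    episode_spec=(("NSR", 500), ("AF", 500), ("NSR", 500))))
decisions = detect_stream(stream)            # threshold 0.639

c = confusion(decisions, list(stream.labels))
m = metrics(c)
print(f"TP={c.tp} TN={c.tn} FP={c.fp} FN={c.fn}")
print(f"Se={m.se:.4f} Sp={m.sp:.4f} PPV={m.ppv:.4f} ACC={m.acc:.4f}")

h, ref = zip(*[(d.h, stream.labels[d.beat_index])
               for d in decisions if d.label != WARMUP])
curve = roc_sweep(np.array(h), list(ref))
print(f"AUC={curve.auc:.4f} best_threshold={curve.best_threshold:.3f}")
```

prints

```
TP=420 TN=827 FP=45 FN=80
Se=0.8400 Sp=0.9484 PPV=0.9032 ACC=0.9089
AUC=0.9721 best_threshold=0.247
```

The 1500-beat record holds a 500-beat AF episode between two sinus
segments. Warm-up beats (the first 128) are excluded from the tally.
Most missed AF beats (FN) sit at the episode edges, where the 127-word
window still mixes both rhythms — the detector's inherent latency of
about half a window (~65 beats). The AUC of 0.97 shows the entropy
separates the rhythms well; the best threshold on this short synthetic
record differs from 0.639 because the synthetic sinus rhythm is cleaner
than long-term clinical recordings.

The same pipeline is available from the shell:

```sh
afdetect simulate --spec "NSR:500,AF:500,NSR:500" --seed 42 --out beats.csv
afdetect detect   --input beats.csv --threshold 0.639 --output decisions.csv
afdetect eval     --decisions decisions.csv --reference beats.csv
afdetect roc      --input beats.csv --out roc.csv
```

Beat files are headered CSV (`rr_ms[,label][,time_s]`); rdann-style
whitespace annotation exports (`time [sample] code`, rhythm codes such
as `(AFIB` / `(N`) are read with `--format rdann_text`.

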