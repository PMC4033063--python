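# synergait

Muscle-synergy analysis of locomotion EMG: extraction of motor modules from
surface EMG recorded during treadmill walking, and a systematic comparison
of how the *data structure* fed to the factorization — single step cycles,
averaged cycles, or concatenated cycles — shapes the result.

## Who this is for

Researchers in motor control, gait analysis, and rehabilitation engineering
who extract muscle synergies from multi-channel EMG and need to decide how
many step cycles to analyze and how to arrange them. The package ships a
complete, tested pipeline plus a synthetic gait-EMG generator with a known
ground truth, so every stage can be validated end to end.

## The model

Multi-muscle envelope EMG is approximated by a small set of motor modules:

```
X(k) ≈ Xr(k) = S · P(k)
```

where `X` is the muscles × time envelope matrix (10 lower-limb muscles on a
200-point 0–100% step-cycle grid), `S` (muscles × N) holds nonnegative
muscle weightings and `P` (N × time) nonnegative activation signals, with
N < M. Factors are estimated by Lee–Seung multiplicative updates for the
squared Frobenius error, best of 20 random restarts. Reconstruction quality
is the variability accounted for,

```
VAF = 1 − SSE / SST ,   SST = Σ X²  (uncentered, pooled)
```

and the number of modules is the smallest N whose VAF clears 90% where the
VAF curve's slope flattens (gain to N+1 below 0.05). Module sets are
compared by the normalized scalar product of best-matched pairs (globally
optimal assignment), and cross-reconstruction fixes the weightings from one
stretch of walking while refitting only the activations on another.

The pipeline covers:

- **synthetic recordings** — envelopes composed from a 5-module ground
  truth with step-to-step gain, timing, and noise variability, modulated
  onto a 20–500 Hz noise carrier at 2000 Hz, plus a tibial accelerometer
  channel with one impact transient per heel strike;
- **preprocessing** — zero-lag Butterworth filtering (20–500 Hz band-pass,
  rectification, 10 Hz low-pass), accelerometer-based step segmentation,
  time normalization to 200 points, peak normalization to unit channel
  amplitude;
- **data structures** — single (`SNG`), averaged (`AVR`), and concatenated
  (`CNC`) cycle matrices for any cycle count k ∈ {2, 3, 5, 10, 20, 40};
- **factorization** — free NMF, fixed-weightings / fixed-activations
  variants, random-factor VAF baselines;
- **analysis** — similarity, matching, dimensionality selection, matched
  averaging;
- **study pipeline** — the full three-experiment design on a 12-subject
  synthetic cohort, emitting tidy CSV tables.

## Worked example

```python
import numpy as np
import synergait as sg
from synergait.structures import concatenated
from synergait.analysis import match, select_dimensionality

# one synthetic subject: 40 step cycles, 10 muscles, 2000 Hz
rec = sg.generate_subject(sg.SimulationConfig(seed=42))
cycles = sg.preprocess_recording(rec)

# five motor modules from the 40-cycle concatenation
X = concatenated(cycles, k=40)
res = sg.nmf(X, n_modules=5, restarts=20, seed=1)
print(f"overall VAF: {res.vaf_overall:.3f}")

n, curve, _ = select_dimensionality(X, seed=7, restarts=5, max_iter=500)
print(f"selected dimensionality: {n}")
print("VAF curve:", np.round(curve[:6], 3))

# recovered weightings vs. the generating ground truth
rep = match(rec.ground_truth.weightings, res.S)
print("module match similarities:", np.round(rep.similarities, 3))
```

Output:

```
overall VAF: 0.994
selected dimensionality: 5
VAF curve: [0.534 0.718 0.837 0.931 0.994 0.996]
module match similarities: [0.999 0.993 0.99  0.994 0.931]
```

Five modules reconstruct 99.4% of the envelope energy; the VAF curve rises
steeply up to N = 5 and flattens, so dimensionality selection returns 5;
and the extracted weightings match the generating modules at similarities
0.93–1.00 (M5, the diffuse transition-phase module, is hardest).

The same pipeline is available from the shell:

```sh
synergait simulate --seed 42 --out rec.tsv
synergait preprocess rec.tsv --out cycles.npz
synergait build cycles.npz --structure cnc --k 40 --out cnc40.tsv
synergait extract cnc40.tsv --n-modules 5 --out-prefix modules
synergait run-study --n-subjects 12 --seed 0 --out study/
```

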