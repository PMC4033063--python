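# Methods

## Motor-module model

Envelope EMG from M muscles is modeled as a nonnegative linear combination
of N < M motor modules, `X ≈ S · P`: the weightings `S` (M × N) describe
*which* muscles each module recruits, the activation signals `P` (N × T)
describe *when* each module is active across the step cycle. Both factors
are estimated by the Lee–Seung multiplicative update rules for the squared
Frobenius error. The updates preserve nonnegativity and never increase the
objective; a small epsilon (1e-12) in the denominators guards against
division by zero. Each fit starts from uniform(0,1) factors and keeps the
best of `restarts` runs by final objective (ties break to the earliest
restart); convergence is declared when the relative objective decrease
falls below `tol` or `max_iter` is reached. Returned weighting columns are
max-normalized, with the inverse scaling folded into `P`, so weightings
are comparable across runs; similarity measures are scale-free anyway.

Reconstruction quality is the variability accounted for,
`VAF = 1 − SSE/SST` with uncentered `SST = ΣX²` pooled over all muscles
and samples — the dominant convention in the synergy literature (a
centered option exists behind a flag). Per-muscle VAF uses row-wise sums,
which pool exactly to the overall value.

Constrained variants update only one factor: fixed weightings for
cross-reconstruction (a convex nonnegative regression in `P`, so few
restarts are needed) and fixed activations for the mirror case. The
random-factor baselines pair an extracted factor with a uniform random
counterpart, either scaled to the data's mean amplitude (`optimize=False`)
or refined by 1000 multiplicative updates of the random factor alone
(`optimize=True`). The two options bracket two readings of "randomly
generated" baselines: unoptimized random factors yield VAF ≈ 0.32–0.37 on
default synthetic subjects, while optimizing the random factor turns the
baseline into a constrained fit that can approach the free-NMF VAF. The
cohort tables report the unoptimized variant.

## Dimensionality selection

Free NMF is run for N = 1..9 and the selected dimensionality is the
smallest N with `VAF(N) ≥ 0.90` and `VAF(N+1) − VAF(N) < 0.05` — an
explicit operationalization of "the elbow of the VAF curve plus a 90%
floor". Both thresholds are arguments. If no N qualifies, the maximum is
returned with a warning flag. The VAF curve is returned for audit; it is
non-decreasing in N up to restart noise (tolerance 0.005 in tests).

## Similarity and matching

Module vectors are compared by the normalized scalar product
`u·v / (‖u‖‖v‖)` — 1 for identical shapes, 0 for disjoint support,
scale-free. Two module sets are matched by the bijection maximizing total
similarity, found by optimal assignment (Hungarian algorithm) rather than
greedy pairing, which would be order-dependent. Averaging factorizations
across runs first aligns each run's modules to a reference (the
factorization of the full 40-cycle concatenation; when a synthetic ground
truth is available the reference itself is ordered against it, so module
labels M1–M5 are stable).

## Synthetic gait EMG

The generator emulates a 60 s treadmill-walking recording: ~44 s of signal
from 40 step cycles of mean 1.1 s (lognormal, CV 0.04), ten muscles
(TA, SO, GL, GM, VL, VM, RF, BF, ST, GX) at 2000 Hz, one tibial
vertical-acceleration channel.

Per cycle, the noiseless envelope is `W · diag(g) · T`: `W` the 10 × 5
ground-truth weightings, `g` lognormal per-module gains (mean 1, CV 0.10),
`T` activation templates built from Gaussian bursts on the cyclic 0–100%
grid with burst centers jittered by a zero-mean normal (SD 2% of cycle).
Additive normal noise (SD 5% of each channel's noiseless peak) is
truncated at zero. Raw EMG is the envelope resampled to the cycle duration
and multiplied by a zero-mean unit-variance Gaussian carrier band-limited
to 20–500 Hz. All dispersion parameters are configurable; the defaults
above are the package's committed study conditions.

The five default modules follow the canonical organization of walking
synergies: knee extensors + GX at weight acceptance (~10% cycle),
plantarflexors at push-off (~40%), TA + RF across swing (~78%), hamstrings
at terminal swing (~97%, wrapping), and a diffuse ankle/RF/GX module with
small bursts at the step transitions and a broader one near 58%. Burst
widths and weighting supports are balanced so each module carries a
meaningful, partly unique energy share; this mirrors real walking data,
where each synergy explains enough variance for VAF-based selection to
resolve it, and makes the five-module structure recoverable by the elbow
rule on noiseless and default-noise data.

The accelerometer channel is a gait-locked sinusoid (one period per cycle,
representing smooth leg-swing acceleration) plus small white noise, with a
damped 15 Hz cosine transient at every heel strike whose amplitude is 10×
the baseline SD. The cosine phase puts the waveform peak at the strike
itself and the 20 ms decay keeps ringing below detection thresholds; 50 ms
of padding on both ends keeps the terminal transients observable. With a
purely Gaussian baseline a 3-robust-SD threshold detector cannot reach
perfect precision over ~10⁵ samples, so the bounded sinusoidal baseline is
what makes exact step segmentation well-posed in the simulation.

**What the generator does not model:** electrode placement and crosstalk,
motion artifacts, 12-bit quantization, left-leg activity, kinematics or
ground-reaction forces, EMG spectral shape beyond band limits — and,
importantly, any slow non-stationarity of the weightings themselves.
Passing tests therefore show that the pipeline recovers the *stationary*
generative structure; they do not certify behavior on real EMG whose
modules drift over time (see Limitations).

## Preprocessing

"Zero-lag" filtering is a second-order Butterworth design applied forward
and backward (squared magnitude response, zero phase). The EMG envelope
chain is 20–500 Hz band-pass → full-wave rectification → 10 Hz low-pass,
clipped at zero because bidirectional filtering can undershoot. Step
cycles are the spans between consecutive accelerometer impacts, detected
on the 60 Hz low-passed trace as local maxima above median + 3 robust SDs
(1.4826 × MAD), pruned to a minimum separation of half the provisional
median inter-peak interval; a bypass accepts externally supplied
boundaries. Each cycle is linearly interpolated onto 200 points (0–100%
of the cycle; linear interpolation keeps the operator exactly testable on
ramps and idempotent on grid-sized input). Peak normalization — each
channel divided by its maximum — is applied within each constructed data
structure, not once per recording (a record-wide option exists for
sensitivity analysis). Zero-phase filtering of the asymmetric impact
transient shifts detected peaks by a few samples; detection is accurate to
well under 10 ms but not sample-exact.

## Study pipeline

Three experiments per subject, on the first 40 detected cycles:

1. **Structure comparison** — 5-module NMF on AVR and CNC at
   k ∈ {2, 3, 5, 10, 20, 40} plus each single cycle; per-condition VAF.
2. **Similarity** — best-pair matched similarities across cycle counts
   within each structure (weightings always; activations where the
   activation grids coincide, i.e. SNG and AVR) and across structures at
   each cycle count, with SNG represented by its matched-average modules.
3. **Cross-reconstruction** — weightings from first-half (cycles 1–20)
   AVR and CNC structures at k ∈ {2, 3, 5, 10, 20} fixed while refitting
   activations on second-half concatenations and on the full 40-cycle
   concatenation.

N is fixed at 5 for all comparisons. Every NMF condition's seed derives
from the subject seed and a content hash of the input matrix, so equal
inputs always factorize identically and full reruns are byte-identical.
Cohort runs default to 12 subjects with per-subject sub-seeds of one
master seed. Inferential statistics are out of scope; the tidy tables
carry complete provenance so any stats package can compute them.

Pipeline NMF settings default to 5 restarts, 500 iterations, tolerance
1e-5 — problem sizes chosen so a full cohort completes in about a minute
on one CPU while leaving VAF and similarity estimates stable to the third
decimal; standalone extractions default to the stricter 20 restarts and
1000 iterations.

## Numerical and design notes

- Exact low-rank nonnegative data admit a continuum of exact
  factorizations when supports overlap, so factor similarity between
  *different* matrices built from identical cycles (e.g. concatenations of
  different lengths) converges near, but not to, 1. Comparisons of
  *identical* matrices are exact by the content-seeding rule above.
- The acceptance-style VAF bounds use the minimum across structures, so a
  single bound covers SNG, AVR, and CNC.
- All-zero channels pass through peak normalization unchanged with a
  logged warning; all-zero matrices are rejected before factorization.
- Degenerate inputs (SST = 0, zero vectors in similarity, cycles shorter
  than 2 samples, cutoffs at or above Nyquist) raise errors naming the
  offending quantity.

## Limitations

- Ground-truth weightings are time-invariant within a recording. The
  advantage of long concatenation windows for cross-reconstruction is
  therefore much smaller in simulation than in real walking data, where
  slow drift penalizes weightings estimated from averages or short
  stretches. The pipeline measures the contrast either way; simulated
  effect sizes for that one contrast are near zero.
- The cycle-duration distribution (mean 1.1 s, CV 0.04) is plausible for
  preferred-speed treadmill walking but not calibrated to any cohort.
- Detection thresholds are tuned for the simulated accelerometer; real
  accelerometry with large non-impact excursions may need the boundary
  bypass.
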