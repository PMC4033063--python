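"""Synthetic gait-EMG generator.

Emulates a treadmill-walking recording: 10 lower-limb muscles sampled at
2000 Hz plus one tibial vertical-acceleration channel. Muscle envelopes are
composed from a small set of ground-truth motor modules — fixed muscle
weightings driven by burst-like activation templates on a 0-100% step-cycle
grid — with controllable step-to-step amplitude, timing, and additive-noise
variability. Raw EMG is obtained by modulating a band-limited noise carrier
with the envelope; the accelerometer channel carries one impact transient
per heel strike.

The generative model mirrors the factorization model: for cycle ``c`` the
noiseless envelope is ``W @ diag(g_c) @ T_c`` where ``W`` are the muscle
weightings, ``g_c`` per-cycle module gains, and ``T_c`` the activation
templates with jittered burst centers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

MUSCLES = ("TA", "SO", "GL", "GM", "VL", "VM", "RF", "BF", "ST", "GX")
N_GRID = 200  # samples per time-normalized step cycle (0-100%)

# percent-of-cycle grid the activation templates are evaluated on
_GRID = np.arange(N_GRID) * (100.0 / N_GRID)


def _gaussian_bursts(bursts: Sequence[tuple], centers: np.ndarray) -> np.ndarray:
    """Sum of Gaussian bursts on the cyclic 0-100% grid.

    ``bursts`` is a sequence of (center, width, amplitude) triples in percent
    of cycle; ``centers`` supplies the (possibly jittered) burst centers.
    Wrap-around is handled by summing the three nearest periodic images.
    """
    out = np.zeros(N_GRID)
    for (_, width, amp), c in zip(bursts, centers):
        for off in (-100.0, 0.0, 100.0):
            out += amp * np.exp(-0.5 * ((_GRID - c + off) / width) ** 2)
    return out


@dataclass(frozen=True)
class GroundTruthModel:
    """Ground-truth muscle weightings and activation templates.

    ``weightings`` is muscles x n_modules with each column max-normalized to
    1; ``bursts`` parameterizes each module's activation template as Gaussian
    bursts (center %, width %, amplitude) on the cyclic 0-100% grid. The
    sampled ``activation_templates`` (n_modules x 200) are derived from the
    bursts and max-normalized per row.
    """

    muscle_names: tuple
    weightings: np.ndarray
    bursts: tuple
    activation_templates: np.ndarray = field(init=False)
    # per-module scale that maps the raw burst sum to a max-1 template;
    # reused for jittered templates so amplitudes stay commensurate
    _template_scale: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        W = np.asarray(self.weightings, dtype=float)
        if W.ndim != 2 or W.shape[0] != len(self.muscle_names):
            raise ValueError("weightings must be muscles x n_modules")
        if self.n_modules < 1:
            raise ValueError("need at least one module")
        if np.any(W < 0):
            raise ValueError("weightings must be nonnegative")
        W = W / W.max(axis=0)
        raw = np.array([_gaussian_bursts(b, np.array([c for c, _, _ in b]))
                        for b in self.bursts])
        scale = raw.max(axis=1)
        object.__setattr__(self, "weightings", W)
        object.__setattr__(self, "_template_scale", scale)
        object.__setattr__(self, "activation_templates", raw / scale[:, None])

    @property
    def n_modules(self) -> int:
        return np.asarray(self.weightings).shape[1]

    def jittered_templates(self, center_shifts: np.ndarray) -> np.ndarray:
        """Templates with burst centers shifted by ``center_shifts`` (% cycle).

        ``center_shifts[m][j]`` shifts burst j of module m. Scaling matches
        the unjittered templates (not re-normalized), so per-cycle amplitude
        variation is carried by the gains alone.
        """
        rows = []
        for m, b in enumerate(self.bursts):
            centers = np.array([c for c, _, _ in b]) + center_shifts[m]
            rows.append(_gaussian_bursts(b, centers) / self._template_scale[m])
        return np.array(rows)


def default_ground_truth() -> GroundTruthModel:
    """Five-module ground truth for level treadmill walking.

    Module composition follows the canonical organization of walking
    synergies: M1 knee extensors + gluteus at weight acceptance (~10% cycle);
    M2 plantarflexors at push-off (~40%); M3 TA + RF through swing; M4
    hamstrings at terminal swing wrapping into initial contact; M5 a mixed
    ankle/RF/GX module with small bursts at the step transitions and no
    single dominant burst.

    Burst widths and weighting support are balanced so every module carries
    a non-negligible, partly unique share of the signal energy — mirroring
    real walking data, where each synergy explains enough variance for
    VAF-based dimensionality selection to resolve it.
    """
    # rows: TA SO GL GM VL VM RF BF ST GX
    W = np.array([
        # M1    M2    M3    M4    M5
        [0.02, 0.02, 1.00, 0.02, 0.45],   # TA
        [0.02, 1.00, 0.02, 0.02, 0.80],   # SO
        [0.02, 0.90, 0.02, 0.02, 0.10],   # GL
        [0.02, 0.95, 0.02, 0.02, 0.10],   # GM
        [1.00, 0.02, 0.02, 0.02, 0.02],   # VL
        [0.95, 0.02, 0.02, 0.02, 0.02],   # VM
        [0.25, 0.02, 0.70, 0.02, 0.45],   # RF
        [0.02, 0.02, 0.02, 1.00, 0.02],   # BF
        [0.02, 0.02, 0.02, 0.95, 0.02],   # ST
        [0.25, 0.02, 0.02, 0.10, 1.00],   # GX
    ])
    bursts = (
        ((10.0, 4.0, 1.0),),                                        # M1
        ((40.0, 5.0, 1.0),),                                        # M2
        ((78.0, 7.0, 1.0),),                                        # M3
        ((97.0, 4.0, 1.0),),                                        # M4
        ((2.0, 3.0, 0.35), (58.0, 8.0, 1.0), (97.0, 3.0, 0.35)),    # M5
    )
    return GroundTruthModel(muscle_names=MUSCLES, weightings=W, bursts=bursts)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic walking recording.

    Defaults give 40 step cycles of ~1.1 s (≈44 s, fitting a 60 s window)
    with moderate step-to-step variability: 10% lognormal amplitude jitter
    per cycle and module, 2%-of-cycle normal jitter on burst centers, and
    additive envelope noise at 5% of each channel's peak (truncated at 0).
    """

    n_cycles: int = 40
    cycle_duration_mean: float = 1.1     # s
    cycle_duration_cv: float = 0.04
    fs: float = 2000.0                   # Hz
    gain_cv: float = 0.10
    timing_jitter_sd: float = 2.0        # % of cycle
    envelope_noise_sd: float = 0.05      # fraction of channel peak
    carrier_band: tuple = (20.0, 500.0)  # Hz
    seed: int = 0

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        for name in ("cycle_duration_cv", "gain_cv", "timing_jitter_sd",
                     "envelope_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fs <= 2 * self.carrier_band[1]:
            raise ValueError("fs must exceed twice the upper carrier band edge")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Recording:
    """Raw multi-channel EMG plus tibial acceleration.

    ``emg`` is muscles x samples (arbitrary units), ``accel`` the
    accelerometer trace of equal length. Synthetic recordings carry the true
    cycle-start sample indices (including the terminal boundary) and a
    reference to the generating ground-truth model.
    """

    emg: np.ndarray
    accel: np.ndarray
    fs: float
    muscle_names: tuple = MUSCLES
    true_boundaries: Optional[np.ndarray] = None
    ground_truth: Optional[GroundTruthModel] = None

    def __post_init__(self):
        self.emg = np.atleast_2d(np.asarray(self.emg, dtype=float))
        self.accel = np.asarray(self.accel, dtype=float)
        if self.emg.shape[1] != self.accel.shape[0]:
            raise ValueError("emg and accel must have equal sample counts")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.true_boundaries is not None:
            tb = np.asarray(self.true_boundaries)
            if np.any(np.diff(tb) <= 0):
                raise ValueError("true_boundaries must be strictly increasing")
            self.true_boundaries = tb

    @property
    def n_samples(self) -> int:
        return self.emg.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    """Lognormal samples with the given arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean, dtype=float)
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def generate_cycle_envelopes(model: GroundTruthModel, config: SimulationConfig):
    """Per-cycle muscle envelopes on the 200-point grid.

    Returns ``(envelopes, durations)`` where ``envelopes`` is
    n_cycles x muscles x 200 and ``durations`` the per-cycle durations in
    seconds, drawn lognormal with mean ``cycle_duration_mean`` and CV
    ``cycle_duration_cv``. For each cycle the noiseless envelope is
    ``W @ diag(gains) @ templates`` with lognormal gains (mean 1, CV
    ``gain_cv``) and burst centers jittered by a normal with SD
    ``timing_jitter_sd`` percent of cycle; additive normal noise (SD
    ``envelope_noise_sd`` of each channel's noiseless peak) is truncated
    at zero.
    """
    rng = np.random.default_rng([config.seed, 0x45564E])  # envelope substream
    n_c, n_mod = config.n_cycles, model.n_modules
    M = len(model.muscle_names)
    W = model.weightings

    durations = _lognormal(rng, config.cycle_duration_mean,
                           config.cycle_duration_cv, n_c)
    gains = _lognormal(rng, 1.0, config.gain_cv, (n_c, n_mod))

    clean = W @ model.activation_templates
    chan_peak = clean.max(axis=1)

    env = np.empty((n_c, M, N_GRID))
    for c in range(n_c):
        if config.timing_jitter_sd > 0:
            shifts = [rng.normal(0.0, config.timing_jitter_sd, len(b))
                      for b in model.bursts]
            T = model.jittered_templates(shifts)
        else:
            T = model.activation_templates
        e = (W * gains[c]) @ T
        if config.envelope_noise_sd > 0:
            e = e + rng.normal(
                0.0, 1.0, (M, N_GRID)) * (config.envelope_noise_sd
                                          * chan_peak[:, None])
            e = np.clip(e, 0.0, None)
        env[c] = e
    return env, durations


# lead-in before the first and tail after the final heel strike so both
# terminal impact transients are fully representable in the trace
_PAD_S = 0.05
_TAIL_S = 0.05
_IMPACT_FREQ = 15.0   # Hz
_IMPACT_TAU = 0.02    # s decay constant; fast decay keeps ringing below
                      # detection thresholds relative to the 10x peak
_IMPACT_SNR = 10.0    # impact amplitude over baseline SD
_BASE_AMP = 1.0       # gait-locked sinusoidal baseline (leg-swing sway)
_BASE_NOISE = 0.1     # white measurement noise on the accelerometer


def _impact_waveform(fs: float) -> np.ndarray:
    # damped cosine: waveform peak sits at the cycle start itself
    t = np.arange(int(round(4 * _IMPACT_TAU * fs))) / fs
    return np.exp(-t / _IMPACT_TAU) * np.cos(2 * np.pi * _IMPACT_FREQ * t)


def synthesize_raw(envelopes: np.ndarray, durations: np.ndarray,
                   config: SimulationConfig) -> Recording:
    """Turn per-cycle envelopes into a raw Recording.

    Each cycle's 200-point envelope is resampled to its duration at ``fs``
    and multiplied by a zero-mean, unit-variance noise carrier band-limited
    to ``carrier_band``. The accelerometer channel is a gait-locked
    sinusoidal baseline (one period per cycle, representing smooth
    leg-swing acceleration) plus white measurement noise, with one
    damped-oscillation impact transient at every cycle start (terminal
    boundary included); short padding on both ends keeps the terminal
    transients observable.
    """
    envelopes = np.asarray(envelopes, dtype=float)
    if np.any(envelopes < 0):
        raise ValueError("envelopes must be nonnegative")
    n_c, M, _ = envelopes.shape
    fs = config.fs

    samples = np.rint(np.asarray(durations) * fs).astype(int)
    if np.any(samples < 10):
        raise ValueError("cycle durations produce fewer than 10 samples")
    pad = int(round(_PAD_S * fs))
    boundaries = pad + np.concatenate([[0], np.cumsum(samples)])
    tail = int(round(_TAIL_S * fs))
    n_total = boundaries[-1] + tail

    env_full = np.zeros((M, n_total))
    for c in range(n_c):
        n_s = samples[c]
        pos = np.linspace(0.0, N_GRID - 1, n_s)
        for m in range(M):
            env_full[m, boundaries[c]:boundaries[c + 1]] = np.interp(
                pos, np.arange(N_GRID), envelopes[c, m])

    rng = np.random.default_rng([config.seed, 0x524157])  # raw-signal substream
    lo, hi = config.carrier_band
    sos = signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    carrier = signal.sosfiltfilt(sos, rng.standard_normal((M, n_total)), axis=1)
    carrier -= carrier.mean(axis=1, keepdims=True)
    carrier /= carrier.std(axis=1, keepdims=True)
    emg = env_full * carrier

    accel = _BASE_NOISE * rng.standard_normal(n_total)
    for c in range(n_c):
        n_s = samples[c]
        phase = 2 * np.pi * np.arange(n_s) / n_s
        accel[boundaries[c]:boundaries[c + 1]] += _BASE_AMP * np.sin(phase)
    baseline_sd = float(accel.std())
    w = _impact_waveform(fs)
    for b in boundaries:
        seg = min(len(w), n_total - b)
        accel[b:b + seg] += _IMPACT_SNR * baseline_sd * w[:seg]

    return Recording(emg=emg, accel=accel, fs=fs,
                     true_boundaries=boundaries)


def generate_subject(config: Optional[SimulationConfig] = None,
                     model: Optional[GroundTruthModel] = None) -> Recording:
    """One synthetic walking subject: model -> envelopes -> raw recording."""
    config = config if config is not None else SimulationConfig()
    model = model if model is not None else default_ground_truth()
    env, dur = generate_cycle_envelopes(model, config)
    rec = synthesize_raw(env, dur, config)
    rec.ground_truth = model
    return rec
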