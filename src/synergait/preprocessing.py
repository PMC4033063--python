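"""EMG preprocessing and step-cycle segmentation.

Raw recording -> linear envelopes (20-500 Hz band-pass, full-wave
rectification, 10 Hz low-pass) -> heel-strike detection from the tibial
accelerometer (60 Hz low-pass, MAD-thresholded peak picking) -> per-cycle
time normalization onto a 200-point 0-100% grid.

All filtering is zero-lag: a second-order Butterworth design applied
forward and backward, which cancels phase distortion at the cost of
squaring the magnitude response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from synergait.synthetic import Recording, N_GRID

logger = logging.getLogger(__name__)


@dataclass
class StepCycleSet:
    """Segmented, time-normalized envelope cycles.

    ``cycles`` is n_cycles x muscles x 200 (nonnegative envelope amplitude;
    peak normalization is applied later, when factorization inputs are
    built). ``boundaries`` are the sample indices used for segmentation.
    """

    cycles: np.ndarray
    muscle_names: tuple
    boundaries: np.ndarray
    fs: float

    def __post_init__(self):
        self.cycles = np.asarray(self.cycles, dtype=float)
        if self.cycles.ndim != 3 or self.cycles.shape[2] != N_GRID:
            raise ValueError(f"cycles must be n_cycles x muscles x {N_GRID}")
        if np.any(self.cycles < 0):
            raise ValueError("cycle envelopes must be nonnegative")

    @property
    def n_cycles(self) -> int:
        return self.cycles.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.cycles.shape[1]


def zero_lag_butterworth(x, fs: float, kind: str, cutoff, order: int = 2):
    """Forward-backward Butterworth filter (zero phase shift).

    ``kind`` is ``"low"`` or ``"band"``; ``cutoff`` a scalar Hz or an
    (lo, hi) pair. The stated ``order`` is that of the one-pass design; the
    bidirectional application doubles the effective magnitude order.
    """
    x = np.asarray(x, dtype=float)
    nyq = fs / 2.0
    cut = np.atleast_1d(np.asarray(cutoff, dtype=float))
    for c in cut:
        if not 0 < c < nyq:
            raise ValueError(
                f"cutoff {c} Hz outside (0, Nyquist={nyq} Hz)")
    if kind == "low":
        sos = sps.butter(order, cut[0], btype="low", fs=fs, output="sos")
    elif kind == "band":
        sos = sps.butter(order, cut, btype="band", fs=fs, output="sos")
    else:
        raise ValueError(f"unknown filter kind {kind!r}")
    return sps.sosfiltfilt(sos, x, axis=-1)


def envelope(emg, fs: float, band=(20.0, 500.0), lowpass: float = 10.0):
    """Linear envelope: band-pass, full-wave rectify, low-pass, clip at 0.

    Forward-backward low-pass filtering can undershoot around sharp
    rectified peaks, so the output is clipped at zero.
    """
    if fs <= 1000:
        raise ValueError("fs must exceed 1000 Hz for the 20-500 Hz band")
    x = zero_lag_butterworth(emg, fs, "band", band, order=2)
    x = np.abs(x)
    x = zero_lag_butterworth(x, fs, "low", lowpass, order=2)
    return np.clip(x, 0.0, None)


def detect_cycles(accel, fs: float) -> np.ndarray:
    """Heel-strike indices from a tibial vertical-acceleration trace.

    The trace is low-pass filtered at 60 Hz; candidate impacts are local
    maxima exceeding median + 3 robust SDs (1.4826 x MAD). A provisional
    peak set establishes the median inter-peak interval, after which peaks
    closer than half that interval are pruned (larger peak wins).
    """
    accel = np.asarray(accel, dtype=float)
    if accel.shape[0] < 2 * fs:
        raise ValueError("need at least 2 s of accelerometer signal")
    x = zero_lag_butterworth(accel, fs, "low", 60.0, order=2)
    med = np.median(x)
    mad_sd = 1.4826 * np.median(np.abs(x - med))
    thr = med + 3.0 * mad_sd
    peaks, _ = sps.find_peaks(x, height=thr)
    if len(peaks) < 2:
        raise ValueError("insufficient step events")
    min_sep = 0.5 * np.median(np.diff(peaks))
    peaks, _ = sps.find_peaks(x, height=thr, distance=max(1, min_sep))
    if len(peaks) < 2:
        raise ValueError("insufficient step events")
    return peaks


def time_normalize(segment) -> np.ndarray:
    """Linearly interpolate each channel onto 200 points (first..last sample)."""
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    n = seg.shape[1]
    if n < 2:
        raise ValueError("segment must contain at least 2 samples")
    pos = np.linspace(0.0, n - 1, N_GRID)
    idx = np.arange(n)
    return np.stack([np.interp(pos, idx, row) for row in seg])


def peak_normalize(matrix) -> np.ndarray:
    """Divide each channel (row) by its maximum so amplitudes span 0-1.

    All-zero rows are returned unchanged (with a logged warning); negative
    entries are rejected.
    """
    X = np.asarray(matrix, dtype=float)
    if np.any(X < 0):
        raise ValueError("peak normalization requires nonnegative input")
    peaks = X.max(axis=-1, keepdims=True)
    zero = (peaks == 0).ravel()
    if zero.any():
        logger.warning("peak_normalize: %d all-zero channel(s) left unchanged",
                       int(zero.sum()))
    safe = np.where(peaks == 0, 1.0, peaks)
    return X / safe


def preprocess_recording(recording: Recording, n_cycles: int = 40,
                         use_true_boundaries: bool = False) -> StepCycleSet:
    """Full preprocessing: envelopes, segmentation, time normalization.

    Segmentation uses the accelerometer-detected heel strikes unless
    ``use_true_boundaries`` is set and the recording carries ground-truth
    boundaries (synthetic data). The first ``n_cycles`` cycles are retained;
    fewer available cycles is an error. Peak normalization is deferred to
    factorization-input construction.
    """
    env = envelope(recording.emg, recording.fs)
    if use_true_boundaries:
        if recording.true_boundaries is None:
            raise ValueError("recording carries no true boundaries")
        bounds = np.asarray(recording.true_boundaries)
    else:
        bounds = detect_cycles(recording.accel, recording.fs)
    n_avail = len(bounds) - 1
    if n_avail < n_cycles:
        raise ValueError(
            f"only {n_avail} cycles available, {n_cycles} requested")
    bounds = bounds[:n_cycles + 1]
    cycles = np.stack([
        time_normalize(env[:, bounds[i]:bounds[i + 1]])
        for i in range(n_cycles)
    ])
    return StepCycleSet(cycles=cycles, muscle_names=recording.muscle_names,
                        boundaries=bounds, fs=recording.fs)
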