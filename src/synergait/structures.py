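"""Factorization input construction: single, averaged, concatenated cycles.

From a StepCycleSet, three kinds of envelope matrices can be built for any
cycle count k and starting offset:

* SNG — each step cycle on its own (muscles x 200),
* AVR — the pointwise mean of k consecutive cycles (muscles x 200),
* CNC — k consecutive cycles placed side by side (muscles x 200k).

Each constructed matrix is peak-normalized per muscle within the structure,
so every nonzero channel spans 0-1 in amplitude. Normalizing once over the
whole record instead is available via ``normalize="record"`` for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from synergait.preprocessing import StepCycleSet, peak_normalize

STRUCTURES = ("SNG", "AVR", "CNC")


@dataclass
class EnvelopeMatrix:
    """A muscles x T envelope matrix tagged with its construction."""

    values: np.ndarray
    muscle_names: tuple
    structure_tag: str
    k: int
    offset: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.structure_tag not in STRUCTURES:
            raise ValueError(f"structure_tag must be one of {STRUCTURES}")
        expected = 200 * self.k if self.structure_tag == "CNC" else 200
        if self.values.shape[1] != expected:
            raise ValueError(
                f"{self.structure_tag} with k={self.k} requires "
                f"{expected} columns, got {self.values.shape[1]}")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")

    @property
    def shape(self):
        return self.values.shape


def _check_range(cycle_set: StepCycleSet, k: int, offset: int) -> None:
    if k < 1:
        raise ValueError("k must be >= 1")
    if offset < 0 or offset + k > cycle_set.n_cycles:
        raise ValueError(
            f"cycles [{offset}, {offset + k}) out of range; "
            f"{cycle_set.n_cycles} cycles available")


def _maybe_normalize(values: np.ndarray, cycle_set: StepCycleSet,
                     normalize: str) -> np.ndarray:
    if normalize == "structure":
        return peak_normalize(values)
    if normalize == "record":
        peaks = cycle_set.cycles.max(axis=(0, 2))
        safe = np.where(peaks == 0, 1.0, peaks)
        return values / safe[:, None]
    raise ValueError("normalize must be 'structure' or 'record'")


def single_cycles(cycle_set: StepCycleSet,
                  normalize: str = "structure") -> List[EnvelopeMatrix]:
    """One SNG matrix per cycle, each peak-normalized independently."""
    return [
        EnvelopeMatrix(
            values=_maybe_normalize(cycle_set.cycles[i], cycle_set, normalize),
            muscle_names=cycle_set.muscle_names,
            structure_tag="SNG", k=1, offset=i)
        for i in range(cycle_set.n_cycles)
    ]


def averaged(cycle_set: StepCycleSet, k: int, offset: int = 0,
             normalize: str = "structure") -> EnvelopeMatrix:
    """Pointwise mean of cycles ``offset .. offset+k-1``, peak-normalized."""
    _check_range(cycle_set, k, offset)
    mean = cycle_set.cycles[offset:offset + k].mean(axis=0)
    return EnvelopeMatrix(
        values=_maybe_normalize(mean, cycle_set, normalize),
        muscle_names=cycle_set.muscle_names,
        structure_tag="AVR", k=k, offset=offset)


def concatenated(cycle_set: StepCycleSet, k: int, offset: int = 0,
                 normalize: str = "structure") -> EnvelopeMatrix:
    """Cycles ``offset .. offset+k-1`` side by side, peak-normalized jointly."""
    _check_range(cycle_set, k, offset)
    cat = np.concatenate(list(cycle_set.cycles[offset:offset + k]), axis=1)
    return EnvelopeMatrix(
        values=_maybe_normalize(cat, cycle_set, normalize),
        muscle_names=cycle_set.muscle_names,
        structure_tag="CNC", k=k, offset=offset)
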