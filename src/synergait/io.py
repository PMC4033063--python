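"""File formats: recordings, cycle sets, envelope matrices, factorizations.

Recordings travel as tab-separated text (one header row: time_s, the ten
muscle labels, accel; one row per sample) with an optional JSON sidecar
carrying the sampling rate, generator configuration, and true cycle
boundaries. Matrices are muscle-labeled TSV; cycle sets are an .npz array
plus JSON metadata; reports and manifests are JSON.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from synergait.synthetic import MUSCLES, Recording, SimulationConfig
from synergait.preprocessing import StepCycleSet
from synergait.structures import EnvelopeMatrix
from synergait.factorization import FactorizationResult


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_recording(recording: Recording, path,
                    config: Optional[SimulationConfig] = None) -> Path:
    """Write a Recording as TSV plus a JSON sidecar; returns the TSV path."""
    path = Path(path)
    t = np.arange(recording.n_samples) / recording.fs
    df = pd.DataFrame({"time_s": t})
    for i, name in enumerate(recording.muscle_names):
        df[name] = recording.emg[i]
    df["accel"] = recording.accel
    # %.17g guarantees exact float64 round trip through text
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    meta = {"fs": recording.fs,
            "muscle_names": list(recording.muscle_names),
            "true_boundaries": (None if recording.true_boundaries is None
                                else [int(b) for b in recording.true_boundaries]),
            "config": (dataclasses.asdict(config) if config is not None
                       else None)}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path, muscle_names=MUSCLES) -> Recording:
    """Read a TSV recording; fs from the sidecar or the median time step."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [m for m in (*muscle_names, "accel", "time_s")
               if m not in df.columns]
    if missing:
        raise ValueError(f"missing channel column(s): {', '.join(missing)}")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")

    fs, boundaries = None, None
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        fs = meta.get("fs")
        tb = meta.get("true_boundaries")
        boundaries = None if tb is None else np.asarray(tb, dtype=int)
    if fs is None:
        fs = 1.0 / float(np.median(dt))
    emg = np.stack([df[m].to_numpy() for m in muscle_names])
    return Recording(emg=emg, accel=df["accel"].to_numpy(), fs=float(fs),
                     muscle_names=tuple(muscle_names),
                     true_boundaries=boundaries)


def save_cycle_set(cycle_set: StepCycleSet, path) -> Path:
    """Cycle tensor as .npz with a JSON metadata sidecar."""
    path = Path(path)
    np.savez(path, cycles=cycle_set.cycles,
             boundaries=cycle_set.boundaries)
    meta = {"muscle_names": list(cycle_set.muscle_names),
            "fs": cycle_set.fs, "n_cycles": cycle_set.n_cycles}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_cycle_set(path) -> StepCycleSet:
    path = Path(path)
    with np.load(path if path.suffix == ".npz"
                 else path.with_suffix(path.suffix + ".npz")) as data:
        cycles = data["cycles"]
        boundaries = data["boundaries"]
    meta = json.loads(_sidecar_path(path).read_text())
    return StepCycleSet(cycles=cycles,
                        muscle_names=tuple(meta["muscle_names"]),
                        boundaries=boundaries, fs=meta["fs"])


def write_matrix(matrix: EnvelopeMatrix, path) -> Path:
    """EnvelopeMatrix as TSV with muscle-labeled rows."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=list(matrix.muscle_names))
    df.to_csv(path, sep="\t", header=False)
    meta = {"structure_tag": matrix.structure_tag, "k": matrix.k,
            "offset": matrix.offset}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_matrix(path) -> EnvelopeMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    meta = json.loads(_sidecar_path(path).read_text())
    return EnvelopeMatrix(values=df.to_numpy(dtype=float),
                          muscle_names=tuple(df.index),
                          structure_tag=meta["structure_tag"],
                          k=meta["k"], offset=meta["offset"])


def save_factorization(result: FactorizationResult, prefix) -> None:
    """S and P as TSV (prefix_S.tsv, prefix_P.tsv) + JSON metadata."""
    prefix = Path(prefix)
    np.savetxt(f"{prefix}_S.tsv", result.S, delimiter="\t")
    np.savetxt(f"{prefix}_P.tsv", result.P, delimiter="\t")
    meta = {"vaf_overall": result.vaf_overall,
            "vaf_per_muscle": [float(v) for v in result.vaf_per_muscle],
            "n_iter": result.n_iter, "restarts": result.restarts,
            "seed": result.seed,
            "final_objective": float(result.objective_trace[-1])}
    Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=1))


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, seed: int, config: Optional[dict] = None,
                   inputs: Optional[dict] = None) -> Path:
    """Run manifest: version, master seed, config snapshot, input digests."""
    from synergait import __version__
    manifest = {
        "tool": "synergait",
        "version": __version__,
        "master_seed": seed,
        "config": config,
        "input_digests": {str(k): file_digest(v)
                          for k, v in (inputs or {}).items()},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=1))
    return path
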