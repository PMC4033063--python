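"""Cohort-level study orchestration.

Runs the three experiments of the data-structure comparison on a cohort of
synthetic walking subjects and emits tidy tables:

1. structure comparison — reconstruction quality (VAF) of 5-module NMF on
   single (SNG), averaged (AVR), and concatenated (CNC) inputs built from
   k ∈ {2, 3, 5, 10, 20, 40} consecutive step cycles;
2. intra- and cross-structure module similarity — best-pair matched
   normalized scalar products across cycle counts within a structure and
   across structures at each cycle count;
3. fixed-weightings cross-reconstruction — weightings extracted from the
   first half of the recording (2..20 cycles) reused to reconstruct
   second-half and full-record concatenations, only the activations refit.

Random-factor VAF baselines accompany the first experiment. Descriptive
summaries (means, SDs per condition) replace inferential statistics; the
tidy tables carry full provenance (subject seed + condition) so any stats
package can take over.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from synergait.synthetic import (SimulationConfig, Recording,
                                 default_ground_truth, generate_subject)
from synergait.preprocessing import StepCycleSet, preprocess_recording
from synergait.structures import single_cycles, averaged, concatenated
from synergait.factorization import (FactorizationResult, nmf,
                                     nmf_fixed_weightings, random_baseline)
from synergait.analysis import (match, similarity, permute_result,
                                average_matched_factorizations)

DEFAULT_KS = (2, 3, 5, 10, 20, 40)
DEFAULT_KS_WEIGHTS = (2, 3, 5, 10, 20)
FIRST_HALF, SECOND_HALF = 0, 20  # cycle offsets of the two record halves


def substream_seed(master: int, *keys) -> int:
    """Deterministic sub-seed (< 2^31) from a master seed and labels."""
    ints = [int(master)]
    for k in keys:
        ints.append(zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k))
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2 ** 31))


@dataclass
class StudyTables:
    """Tidy per-subject/per-condition outputs of the three experiments."""

    vaf_table: pd.DataFrame
    similarity_table: pd.DataFrame
    cross_recon_table: pd.DataFrame
    baseline_table: pd.DataFrame

    def write(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.vaf_table.to_csv(out / "vaf_table.csv", index=False)
        self.similarity_table.to_csv(out / "similarity_table.csv", index=False)
        self.cross_recon_table.to_csv(out / "cross_recon_table.csv",
                                      index=False)
        self.baseline_table.to_csv(out / "baseline_table.csv", index=False)

    def summary(self) -> Dict[str, pd.DataFrame]:
        """Descriptive means and SDs per condition."""
        out = {}
        out["vaf"] = (self.vaf_table
                      .groupby(["structure", "k"])["vaf_overall"]
                      .agg(["mean", "std", "count"]).reset_index())
        out["similarity"] = (self.similarity_table
                             .groupby(["comparison", "pair", "vector",
                                       "module"])["similarity"]
                             .agg(["mean", "std", "count"]).reset_index())
        out["cross_recon"] = (self.cross_recon_table
                              .groupby(["donor_structure", "k_weights",
                                        "target"])["vaf"]
                              .agg(["mean", "std", "count"]).reset_index())
        out["baseline"] = (self.baseline_table
                           .groupby(["structure", "mode", "optimize"])["vaf"]
                           .agg(["mean", "std", "count"]).reset_index())
        return out


class SubjectFactorizations:
    """Lazy cache of one subject's factorizations across conditions.

    All experiments share factorizations of the same (structure, k, offset)
    condition; seeds are derived per condition from the subject seed, so
    results are reproducible regardless of evaluation order. NMF settings
    (restarts, iterations, tolerance) are fixed per subject run.
    """

    def __init__(self, cycle_set: StepCycleSet, n_modules: int = 5,
                 seed: int = 0, restarts: int = 5, max_iter: int = 500,
                 tol: float = 1e-5):
        self.cycle_set = cycle_set
        self.n_modules = n_modules
        self.seed = seed
        self.nmf_kw = dict(max_iter=max_iter, tol=tol, restarts=restarts)
        self._cache: Dict[tuple, FactorizationResult] = {}
        self._sng_matrices = single_cycles(cycle_set)

    def _cond_seed(self, X) -> int:
        # seed from the input content: equal envelope matrices factorize
        # identically, whatever condition produced them (rounding keeps
        # ulp-level arithmetic differences, e.g. from averaging identical
        # cycles, from splitting the seed)
        quantized = np.ascontiguousarray(np.round(X.values, 12))
        return substream_seed(self.seed, zlib.crc32(quantized.tobytes()))

    def sng(self, i: int) -> FactorizationResult:
        key = ("SNG", i)
        if key not in self._cache:
            X = self._sng_matrices[i]
            self._cache[key] = nmf(X, self.n_modules,
                                   seed=self._cond_seed(X), **self.nmf_kw)
        return self._cache[key]

    def all_sng(self) -> list:
        return [self.sng(i) for i in range(self.cycle_set.n_cycles)]

    def avr(self, k: int, offset: int = 0) -> FactorizationResult:
        key = ("AVR", k, offset)
        if key not in self._cache:
            X = averaged(self.cycle_set, k, offset)
            self._cache[key] = nmf(X, self.n_modules,
                                   seed=self._cond_seed(X), **self.nmf_kw)
        return self._cache[key]

    def cnc(self, k: int, offset: int = 0) -> FactorizationResult:
        key = ("CNC", k, offset)
        if key not in self._cache:
            X = concatenated(self.cycle_set, k, offset)
            self._cache[key] = nmf(X, self.n_modules,
                                   seed=self._cond_seed(X), **self.nmf_kw)
        return self._cache[key]

    def reference(self) -> FactorizationResult:
        """Full-record concatenation factorization; module-label reference.

        If the cycle set originates from a known ground truth, the
        reference's modules are ordered to match the ground-truth modules
        (M1..M5); otherwise they keep their extraction order.
        """
        key = ("REF",)
        if key not in self._cache:
            ref = self.cnc(self.cycle_set.n_cycles)
            gt = getattr(self.cycle_set, "ground_truth", None)
            if gt is not None and gt.weightings.shape[1] == self.n_modules:
                rep = match(gt.weightings, ref.S)
                ref = permute_result(ref, rep.pairing)
            self._cache[key] = ref
        return self._cache[key]

    def aligned(self, result: FactorizationResult) -> FactorizationResult:
        """Result with modules reordered to the reference's labeling."""
        rep = match(self.reference().S, result.S)
        return permute_result(result, rep.pairing)


def _vaf_rows(subject: str, result: FactorizationResult, structure: str,
              k: int, offset: int, muscle_names) -> dict:
    row = {"subject": subject, "structure": structure, "k": k,
           "offset": offset, "n_modules": result.n_modules,
           "vaf_overall": result.vaf_overall}
    for name, v in zip(muscle_names, result.vaf_per_muscle):
        row[f"vaf_{name}"] = v
    return row


def run_structure_comparison(run: SubjectFactorizations, subject: str = "S01",
                             ks: Sequence[int] = DEFAULT_KS) -> pd.DataFrame:
    """VAF of 5-module NMF per data structure and cycle count.

    Emits one row per AVR and CNC condition (each k) and one row per single
    cycle; cohort summaries average the per-cycle rows.
    """
    names = run.cycle_set.muscle_names
    rows = []
    for i, res in enumerate(run.all_sng()):
        rows.append(_vaf_rows(subject, res, "SNG", 1, i, names))
    for k in ks:
        rows.append(_vaf_rows(subject, run.avr(k), "AVR", k, 0, names))
        rows.append(_vaf_rows(subject, run.cnc(k), "CNC", k, 0, names))
    return pd.DataFrame(rows)


def run_random_baselines(run: SubjectFactorizations, subject: str = "S01",
                         optimize: bool = False,
                         n_iter: int = 1000) -> pd.DataFrame:
    """Random-factor VAF baselines per structure (full-record conditions).

    For each structure the extracted factorization is paired with a random
    counterpart factor: random activations against the extracted weightings
    (``random_P``) and random weightings against the extracted activations
    (``random_S``). SNG baselines are averaged over all single cycles.
    """
    n_c = run.cycle_set.n_cycles
    rows = []
    for mode in ("random_P", "random_S"):
        for structure in ("SNG", "AVR", "CNC"):
            if structure == "SNG":
                vals = []
                for i in range(n_c):
                    res = run.sng(i)
                    rep = random_baseline(
                        self_X(run, "SNG", i), res, mode, optimize=optimize,
                        n_iter=n_iter,
                        seed=substream_seed(run.seed, "base", mode, "SNG", i))
                    vals.append(rep.vaf)
                v = float(np.mean(vals))
            else:
                res = run.avr(n_c) if structure == "AVR" else run.cnc(n_c)
                rep = random_baseline(
                    self_X(run, structure, n_c), res, mode, optimize=optimize,
                    n_iter=n_iter,
                    seed=substream_seed(run.seed, "base", mode, structure))
                v = rep.vaf
            rows.append({"subject": subject, "structure": structure,
                         "mode": mode, "optimize": optimize, "vaf": v})
    return pd.DataFrame(rows)


def self_X(run: SubjectFactorizations, structure: str, k_or_i: int):
    """The envelope matrix a cached factorization was fitted to."""
    if structure == "SNG":
        return run._sng_matrices[k_or_i]
    if structure == "AVR":
        return averaged(run.cycle_set, k_or_i)
    return concatenated(run.cycle_set, k_or_i)


def run_intra_and_cross_similarity(run: SubjectFactorizations,
                                   subject: str = "S01",
                                   ks: Sequence[int] = DEFAULT_KS
                                   ) -> pd.DataFrame:
    """Best-pair module similarities within and across data structures.

    Intra: all pairwise cycle-count combinations within AVR and CNC, and
    all pairwise single-cycle combinations within SNG; weighting similarity
    always, activation similarity where activation lengths agree (SNG and
    AVR, whose activations live on the common 200-point grid). Cross: at
    each cycle count, SNG (matched-average representative) vs AVR and CNC,
    and AVR vs CNC; weightings only. Pairings come from weighting matching;
    module labels follow the full-record reference factorization.
    """
    rows = []
    module_label = [f"M{m + 1}" for m in range(run.n_modules)]

    def intra_pair(A, B, structure, pair_name):
        rep = match(A.S, B.S)
        for m in range(run.n_modules):
            rows.append({"subject": subject, "comparison": "intra",
                         "structure": structure, "pair": pair_name,
                         "vector": "weightings", "module": module_label[m],
                         "similarity": rep.similarities[m]})
        if A.P.shape[1] == B.P.shape[1]:
            for m in range(run.n_modules):
                s = similarity(A.P[m], B.P[rep.pairing[m]])
                rows.append({"subject": subject, "comparison": "intra",
                             "structure": structure, "pair": pair_name,
                             "vector": "activations",
                             "module": module_label[m], "similarity": s})

    # intra, AVR and CNC: across cycle counts
    for structure, getter in (("AVR", run.avr), ("CNC", run.cnc)):
        for a in range(len(ks)):
            for b in range(a + 1, len(ks)):
                A = run.aligned(getter(ks[a]))
                B = run.aligned(getter(ks[b]))
                intra_pair(A, B, structure, f"k{ks[a]}-k{ks[b]}")

    # intra, SNG: across single cycles
    sng = [run.aligned(r) for r in run.all_sng()]
    for a in range(len(sng)):
        for b in range(a + 1, len(sng)):
            intra_pair(sng[a], sng[b], "SNG", f"c{a}-c{b}")

    # cross-structure at each cycle count; SNG enters via its matched average
    S_sng, _ = average_matched_factorizations(sng, run.reference())
    for k in ks:
        S_avr = run.aligned(run.avr(k)).S
        S_cnc = run.aligned(run.cnc(k)).S
        for pair_name, A, B in (("SNG-AVR", S_sng, S_avr),
                                ("SNG-CNC", S_sng, S_cnc),
                                ("AVR-CNC", S_avr, S_cnc)):
            rep = match(A, B)
            for m in range(run.n_modules):
                rows.append({"subject": subject, "comparison": "cross",
                             "structure": f"k{k}", "pair": pair_name,
                             "vector": "weightings",
                             "module": module_label[m],
                             "similarity": rep.similarities[m]})
    return pd.DataFrame(rows)


def run_cross_reconstruction(run: SubjectFactorizations, subject: str = "S01",
                             ks_weights: Sequence[int] = DEFAULT_KS_WEIGHTS,
                             target_ks: Sequence[int] = DEFAULT_KS_WEIGHTS
                             ) -> pd.DataFrame:
    """Fixed-weightings cross-reconstruction between record halves.

    Muscle weightings extracted from the first half (CNC and AVR of
    2..20 cycles starting at cycle 0) are fixed while the activations are
    refit to second-half concatenations of each length and to the full
    40-cycle concatenation.
    """
    cs = run.cycle_set
    targets = [(f"second_half_k{k}", concatenated(cs, k, SECOND_HALF))
               for k in target_ks]
    targets.append(("full_40", concatenated(cs, cs.n_cycles, 0)))

    rows = []
    for donor_structure in ("CNC", "AVR"):
        for kw in ks_weights:
            donor = (run.cnc(kw, FIRST_HALF) if donor_structure == "CNC"
                     else run.avr(kw, FIRST_HALF))
            for target_name, X in targets:
                res = nmf_fixed_weightings(
                    X, donor.S, max_iter=run.nmf_kw["max_iter"],
                    tol=run.nmf_kw["tol"], restarts=2,
                    seed=substream_seed(run.seed, "xrec", donor_structure,
                                        kw, target_name))
                rows.append({"subject": subject,
                             "donor_structure": donor_structure,
                             "k_weights": kw, "target": target_name,
                             "vaf": res.vaf_overall})
    return pd.DataFrame(rows)


def run_subject(config: Optional[SimulationConfig] = None,
                subject: str = "S01", n_modules: int = 5,
                ks: Sequence[int] = DEFAULT_KS,
                restarts: int = 5, max_iter: int = 500, tol: float = 1e-5,
                use_true_boundaries: bool = False,
                recording: Optional[Recording] = None) -> StudyTables:
    """All three experiments (plus baselines) for one subject."""
    if recording is None:
        recording = generate_subject(config or SimulationConfig())
    cycle_set = preprocess_recording(recording,
                                     use_true_boundaries=use_true_boundaries)
    if recording.ground_truth is not None:
        cycle_set.ground_truth = recording.ground_truth
    seed = (config.seed if config is not None else 0)
    run = SubjectFactorizations(cycle_set, n_modules=n_modules, seed=seed,
                                restarts=restarts, max_iter=max_iter, tol=tol)
    return StudyTables(
        vaf_table=run_structure_comparison(run, subject, ks),
        similarity_table=run_intra_and_cross_similarity(run, subject, ks),
        cross_recon_table=run_cross_reconstruction(run, subject),
        baseline_table=run_random_baselines(run, subject))


def run_cohort(config: Optional[SimulationConfig] = None,
               n_subjects: int = 12, seed: int = 0, n_modules: int = 5,
               ks: Sequence[int] = DEFAULT_KS, restarts: int = 5,
               max_iter: int = 500, tol: float = 1e-5,
               use_true_boundaries: bool = False
               ) -> Tuple[StudyTables, Dict[str, pd.DataFrame]]:
    """Run the full study on a synthetic cohort; tables plus summaries.

    Each subject gets an independent sub-seed of the master seed; identical
    (config, n_subjects, seed) reruns produce identical tables.
    """
    base = config or SimulationConfig()
    tables = []
    for s in range(n_subjects):
        sub_cfg = base.replace(seed=substream_seed(seed, "subject", s))
        tables.append(run_subject(sub_cfg, subject=f"S{s + 1:02d}",
                                  n_modules=n_modules, ks=ks,
                                  restarts=restarts, max_iter=max_iter,
                                  tol=tol,
                                  use_true_boundaries=use_true_boundaries))
    combined = StudyTables(
        vaf_table=pd.concat([t.vaf_table for t in tables], ignore_index=True),
        similarity_table=pd.concat([t.similarity_table for t in tables],
                                   ignore_index=True),
        cross_recon_table=pd.concat([t.cross_recon_table for t in tables],
                                    ignore_index=True),
        baseline_table=pd.concat([t.baseline_table for t in tables],
                                 ignore_index=True))
    return combined, combined.summary()
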