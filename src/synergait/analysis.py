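"""Module similarity, matching, dimensionality selection, and averaging.

Motor modules extracted from different data structures (or different runs)
have arbitrary order and scale, so comparisons go through a normalized
scalar product (cosine similarity, scale-free) and a globally optimal
best-pair assignment between the two module sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from synergait.factorization import FactorizationResult, nmf


@dataclass
class SimilarityReport:
    """Best-pair matching between two module sets.

    ``pairing[i]`` is the index of the set-B module matched to set-A module
    i; ``similarities`` are reported in A's module order.
    """

    pairing: np.ndarray
    similarities: np.ndarray
    mean_similarity: float


def similarity(u, v) -> float:
    """Normalized scalar product (u·v)/(‖u‖‖v‖); scale-free, in [0, 1]
    for nonnegative vectors (1 = identical shape, 0 = disjoint support)."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("undefined similarity for a zero vector")
    return float(u @ v / (nu * nv))


def _columns(A) -> np.ndarray:
    """Module vectors as columns: accepts muscles x N weightings or N x T
    activations (activations are passed transposed by callers)."""
    return np.asarray(A, dtype=float)


def match(A, B) -> SimilarityReport:
    """Globally optimal best-pair matching between two module sets.

    A and B are matrices whose columns are module vectors (weightings) of
    equal count. The bijection maximizing the total normalized scalar
    product is found by optimal assignment.
    """
    A, B = _columns(A), _columns(B)
    if A.shape[1] != B.shape[1]:
        raise ValueError("module counts differ")
    n = A.shape[1]
    sim = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            sim[i, j] = similarity(A[:, i], B[:, j])
    rows, cols = linear_sum_assignment(-sim)
    pairing = np.empty(n, dtype=int)
    pairing[rows] = cols
    sims = sim[np.arange(n), pairing]
    return SimilarityReport(pairing=pairing, similarities=sims,
                            mean_similarity=float(sims.mean()))


def select_dimensionality(X, n_max: int = 9, vaf_threshold: float = 0.90,
                          slope_delta: float = 0.05,
                          seed: Optional[int] = None,
                          restarts: int = 20,
                          max_iter: int = 1000) -> Tuple[int, np.ndarray, bool]:
    """Minimum module count by the VAF-curve elbow plus a 90% floor.

    Runs free NMF for N = 1..n_max and returns ``(selected_n, vaf_curve,
    flagged)``. The selected N is the smallest with VAF(N) >= the threshold
    and a pronounced slope change, operationalized as
    VAF(N+1) - VAF(N) < ``slope_delta``. If no N qualifies, ``n_max`` is
    returned with ``flagged=True``.
    """
    from synergait.structures import EnvelopeMatrix
    M = X.values.shape[0] if isinstance(X, EnvelopeMatrix) else np.asarray(X).shape[0]
    if n_max >= M:
        raise ValueError("n_max must be smaller than the muscle count")
    curve = np.array([
        nmf(X, n, max_iter=max_iter, restarts=restarts,
            seed=None if seed is None else seed + n).vaf_overall
        for n in range(1, n_max + 1)
    ])
    for i, v in enumerate(curve):
        n = i + 1
        if v < vaf_threshold:
            continue
        gain = curve[i + 1] - v if n < n_max else 0.0
        if gain < slope_delta:
            return n, curve, False
    return n_max, curve, True


def permute_result(result: FactorizationResult,
                   pairing: np.ndarray) -> FactorizationResult:
    """Reorder a result's modules so module i becomes old module pairing[i]."""
    return FactorizationResult(
        S=result.S[:, pairing], P=result.P[pairing], Xr=result.Xr,
        vaf_overall=result.vaf_overall, vaf_per_muscle=result.vaf_per_muscle,
        n_iter=result.n_iter, objective_trace=result.objective_trace,
        restarts=result.restarts, seed=result.seed)


def average_matched_factorizations(
        results: Sequence[FactorizationResult],
        reference: FactorizationResult) -> Tuple[np.ndarray, np.ndarray]:
    """Average S and P over runs after matching modules to a reference.

    Each result's modules are aligned to the reference by best-pair matching
    on the muscle weightings, then S and P are averaged element-wise. All
    results must share muscle count, module count, and activation length;
    the reference (typically the full 40-cycle concatenation's
    factorization) must share the weighting shape but may have any
    activation length, since matching uses weightings only.
    """
    if not results:
        raise ValueError("no factorizations to average")
    shapes = {(r.S.shape, r.P.shape) for r in results}
    if len(shapes) != 1 or next(iter(shapes))[0] != reference.S.shape:
        raise ValueError("inconsistent factorization shapes")
    S_acc = np.zeros_like(results[0].S)
    P_acc = np.zeros_like(results[0].P)
    for r in results:
        rep = match(reference.S, r.S)
        S_acc += r.S[:, rep.pairing]
        P_acc += r.P[rep.pairing]
    return S_acc / len(results), P_acc / len(results)
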