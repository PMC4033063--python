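"""Non-negative matrix factorization of envelope matrices.

The motor-module model approximates the muscles x time envelope matrix X as
X ≈ Xr = S · P, where S (muscles x N) holds the nonnegative muscle
weightings of N motor modules and P (N x T) the nonnegative activation
signals. Factors are estimated by the Lee-Seung multiplicative update rules
for the squared Frobenius error,

    P <- P ∘ (SᵀX) / (SᵀS P),    S <- S ∘ (X Pᵀ) / (S P Pᵀ),

which keep both factors nonnegative and never increase the objective.
Constrained variants hold one factor fixed and update only the other —
used for cross-reconstruction (fixed weightings) and for random-factor
baselines. Reconstruction quality is the variability accounted for,
VAF = 1 - SSE/SST with uncentered SST = ΣX² pooled over all muscles and
samples (a centered option exists).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from synergait.structures import EnvelopeMatrix

_EPS = 1e-12  # guards zero denominators in the multiplicative updates


@dataclass
class VAFReport:
    """Pooled and per-muscle variability accounted for."""

    sse: float
    sst: float
    vaf: float
    per_muscle_sse: np.ndarray
    per_muscle_sst: np.ndarray
    per_muscle_vaf: np.ndarray


@dataclass
class FactorizationResult:
    """One NMF solution: factors, reconstruction, fit quality, audit trail."""

    S: np.ndarray                 # muscles x N weightings
    P: np.ndarray                 # N x T activation signals
    Xr: np.ndarray                # reconstruction S @ P
    vaf_overall: float
    vaf_per_muscle: np.ndarray
    n_iter: int
    objective_trace: np.ndarray   # squared Frobenius error per iteration
    restarts: int
    seed: Optional[int]

    @property
    def n_modules(self) -> int:
        return self.S.shape[1]

    def vaf_report(self, X) -> VAFReport:
        return vaf(X, self.Xr)


def _as_array(X) -> np.ndarray:
    if isinstance(X, EnvelopeMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def vaf(X, Xr, centered: bool = False) -> VAFReport:
    """Variability accounted for: 1 - SSE/SST.

    SSE = Σ(X - Xr)²; SST = ΣX² pooled over all entries (uncentered, the
    dominant convention in the synergy literature). ``centered=True``
    subtracts the grand mean from SST instead.
    """
    X, Xr = _as_array(X), _as_array(Xr)
    if X.shape != Xr.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Xr.shape}")
    ref = X - X.mean() if centered else X
    row_sse = ((X - Xr) ** 2).sum(axis=1)
    row_sst = (ref ** 2).sum(axis=1)
    sst = row_sst.sum()
    if sst == 0:
        raise ValueError("degenerate data: SST is zero")
    sse = row_sse.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        per_vaf = np.where(row_sst > 0, 1.0 - row_sse / row_sst, np.nan)
    return VAFReport(sse=float(sse), sst=float(sst), vaf=float(1.0 - sse / sst),
                     per_muscle_sse=row_sse, per_muscle_sst=row_sst,
                     per_muscle_vaf=per_vaf)


def _multiplicative_updates(X, S, P, max_iter, tol, update_S, update_P):
    """Run MU iterations; returns (S, P, objective trace).

    The trace records the squared Frobenius error after each iteration
    (plus the initial value). Convergence: relative objective change < tol.
    """
    obj = float(((X - S @ P) ** 2).sum())
    trace = [obj]
    for _ in range(max_iter):
        if update_P:
            P *= (S.T @ X) / (S.T @ S @ P + _EPS)
        if update_S:
            S *= (X @ P.T) / (S @ (P @ P.T) + _EPS)
        new = float(((X - S @ P) ** 2).sum())
        trace.append(new)
        if obj - new < tol * max(obj, _EPS):
            obj = new
            break
        obj = new
    return S, P, np.array(trace)


def _canonicalize(S, P):
    """Max-normalize S columns, compensating in P; canonical storage form."""
    col_max = S.max(axis=0)
    safe = np.where(col_max == 0, 1.0, col_max)
    return S / safe, P * safe[:, None]


def _run(X, n_modules, max_iter, tol, restarts, seed, S_fixed=None,
         P_fixed=None, canonical=True) -> FactorizationResult:
    X = _as_array(X)
    M, T = X.shape
    if not np.any(X):
        raise ValueError("cannot factorize an all-zero matrix")
    if np.any(X < 0):
        raise ValueError("input must be nonnegative")
    if not 1 <= n_modules <= M:
        raise ValueError(f"n_modules must be in [1, {M}]")

    rng = np.random.default_rng(seed)
    best = None
    for r in range(restarts):
        S = (S_fixed.copy() if S_fixed is not None
             else rng.uniform(0, 1, (M, n_modules)))
        P = (P_fixed.copy() if P_fixed is not None
             else rng.uniform(0, 1, (n_modules, T)))
        S, P, trace = _multiplicative_updates(
            X, S, P, max_iter, tol,
            update_S=S_fixed is None, update_P=P_fixed is None)
        if best is None or trace[-1] < best[2][-1]:
            best = (S, P, trace)

    S, P, trace = best
    if canonical and S_fixed is None and P_fixed is None:
        S, P = _canonicalize(S, P)
    Xr = S @ P
    report = vaf(X, Xr)
    return FactorizationResult(
        S=S, P=P, Xr=Xr, vaf_overall=report.vaf,
        vaf_per_muscle=report.per_muscle_vaf, n_iter=len(trace) - 1,
        objective_trace=trace, restarts=restarts, seed=seed)


def nmf(X, n_modules: int, max_iter: int = 1000, tol: float = 1e-6,
        restarts: int = 20, seed: Optional[int] = None) -> FactorizationResult:
    """Free NMF from uniform(0,1) initializations, best of ``restarts``.

    Returned S columns are max-normalized with compensating row scaling of
    P (similarity comparisons are scale-free; storage is canonical).
    """
    return _run(X, n_modules, max_iter, tol, restarts, seed)


def nmf_fixed_weightings(X, S_fixed, max_iter: int = 1000, tol: float = 1e-6,
                         restarts: int = 3,
                         seed: Optional[int] = None) -> FactorizationResult:
    """NMF with the muscle weightings held fixed; only P is updated.

    The fixed-S problem is a nonnegative least-squares fit of the
    activations, so few restarts suffice. S is returned exactly as supplied.
    """
    S_fixed = np.asarray(S_fixed, dtype=float)
    if np.any(S_fixed < 0):
        raise ValueError("S_fixed must be nonnegative")
    return _run(X, S_fixed.shape[1], max_iter, tol, restarts, seed,
                S_fixed=S_fixed)


def nmf_fixed_activations(X, P_fixed, max_iter: int = 1000, tol: float = 1e-6,
                          restarts: int = 3,
                          seed: Optional[int] = None) -> FactorizationResult:
    """NMF with the activation signals held fixed; only S is updated."""
    P_fixed = np.asarray(P_fixed, dtype=float)
    if np.any(P_fixed < 0):
        raise ValueError("P_fixed must be nonnegative")
    return _run(X, P_fixed.shape[0], max_iter, tol, restarts, seed,
                P_fixed=P_fixed)


def random_baseline(X, component: FactorizationResult, mode: str,
                    optimize: bool = False, n_iter: int = 1000,
                    seed: Optional[int] = None) -> VAFReport:
    """VAF attainable when one factor is replaced by a random matrix.

    ``mode="random_P"`` pairs the extracted weightings S with a random P;
    ``mode="random_S"`` pairs the extracted activations P with a random S.
    With ``optimize=False`` the random factor is uniform(0,1) scaled so the
    reconstruction matches the data's mean amplitude. With ``optimize=True``
    the random factor is refined by ``n_iter`` multiplicative updates
    against X (only that factor updated), which turns the baseline into a
    constrained fit.
    """
    X = _as_array(X)
    rng = np.random.default_rng(seed)
    if mode == "random_P":
        S = component.S.copy()
        P = rng.uniform(0, 1, (component.n_modules, X.shape[1]))
        update_S, update_P = False, True
    elif mode == "random_S":
        P = component.P.copy()
        S = rng.uniform(0, 1, (X.shape[0], component.n_modules))
        update_S, update_P = True, False
    else:
        raise ValueError("mode must be 'random_P' or 'random_S'")

    recon_mean = (S @ P).mean()
    if recon_mean > 0:
        alpha = X.mean() / recon_mean
        if mode == "random_P":
            P *= alpha
        else:
            S *= alpha

    if optimize:
        S, P, _ = _multiplicative_updates(
            X, S, P, max_iter=n_iter, tol=0.0,
            update_S=update_S, update_P=update_P)
    return vaf(X, S @ P)
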