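"""NMF multiplicative updates, VAF, fixed-factor variants, baselines."""

import numpy as np
import pytest
from scipy.optimize import nnls

import synergait as sg
from synergait.factorization import vaf, nmf, nmf_fixed_weightings, \
    nmf_fixed_activations, random_baseline
from synergait.structures import concatenated, averaged


class TestVAF:
    def test_hand_computed_example(self):
        X = np.array([[2.0, 0.0], [0.0, 2.0]])
        Xr = np.array([[1.0, 0.0], [0.0, 1.0]])
        rep = vaf(X, Xr)
        assert rep.sse == 2.0 and rep.sst == 8.0 and rep.vaf == 0.75

    def test_perfect_and_zero_reconstruction(self, rng):
        X = rng.random((4, 30))
        assert vaf(X, X).vaf == 1.0
        assert vaf(X, np.zeros_like(X)).vaf == 0.0

    def test_per_muscle_pools_to_overall(self, rng):
        X, Xr = rng.random((5, 40)), rng.random((5, 40))
        rep = vaf(X, Xr)
        assert np.isclose(rep.per_muscle_sse.sum(), rep.sse)
        assert np.isclose(rep.per_muscle_sst.sum(), rep.sst)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            vaf(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vaf(np.ones((2, 3)), np.ones((3, 2)))


class TestNMF:
    def test_rank_one_recovered_exactly(self, rng):
        X = np.outer(rng.random(6) + 0.1, rng.random(50) + 0.1)
        res = nmf(X, 1, restarts=5, seed=0)
        assert res.vaf_overall >= 0.999

    def test_objective_trace_non_increasing(self, rng):
        X = rng.random((8, 60))
        res = nmf(X, 3, restarts=3, seed=1)
        assert np.all(np.diff(res.objective_trace) <= 1e-9)

    def test_factors_nonnegative_and_canonical(self, rng):
        X = rng.random((8, 60))
        res = nmf(X, 3, restarts=3, seed=1)
        assert np.all(res.S >= 0) and np.all(res.P >= 0)
        assert np.allclose(res.S.max(axis=0), 1.0)
        assert np.allclose(res.Xr, res.S @ res.P, atol=1e-10)

    def test_noiseless_synthetic_cnc_reaches_vaf_099(self,
                                                     noiseless_cycle_set):
        X = concatenated(noiseless_cycle_set, 40)
        res = nmf(X, 5, restarts=5, seed=2)
        assert res.vaf_overall >= 0.99

    def test_vaf_non_decreasing_in_n(self, rng):
        X = rng.random((6, 80)) + 0.05
        vafs = [nmf(X, n, restarts=5, seed=3).vaf_overall
                for n in range(1, 6)]
        assert np.all(np.diff(vafs) >= -0.005)

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError):
            nmf(np.zeros((4, 10)), 2)

    def test_equivalence_with_alternating_nnls_oracle(self, rng):
        """MU-NMF final objective matches an independent alternating-NNLS
        solver within 1% on random 4x6 problems with two modules."""
        def anls(X, n, seed, iters=300):
            r = np.random.default_rng(seed)
            best = np.inf
            for _ in range(10):
                S = r.uniform(0.1, 1, (X.shape[0], n))
                for _ in range(iters):
                    P = np.stack([nnls(S, X[:, j])[0]
                                  for j in range(X.shape[1])], axis=1)
                    S = np.stack([nnls(P.T, X[i])[0]
                                  for i in range(X.shape[0])])
                best = min(best, ((X - S @ P) ** 2).sum())
            return best

        for trial in range(50):
            X = rng.random((4, 6)) + 0.01
            mu = nmf(X, 2, restarts=10, max_iter=3000, tol=1e-10,
                     seed=trial).objective_trace[-1]
            oracle = anls(X, 2, seed=trial, iters=50)
            assert mu <= oracle * 1.01 + 1e-12
            assert oracle <= mu * 1.01 + 1e-12


class TestFixedFactors:
    def test_true_weightings_explain_noiseless_data(self, noiseless_cycle_set,
                                                    model):
        # express the generator weightings in the pipeline's peak-normalized
        # channel coordinates (each channel divided by its envelope peak)
        peaks = (model.weightings @ model.activation_templates).max(
            axis=1, keepdims=True)
        S_true = model.weightings / peaks
        X = concatenated(noiseless_cycle_set, 40)
        res = nmf_fixed_weightings(X, S_true, seed=0)
        assert res.vaf_overall >= 0.99
        assert np.array_equal(res.S, S_true)

    def test_fixed_never_beats_free(self, cycle_set, rng):
        X = averaged(cycle_set, 10)
        free = nmf(X, 4, restarts=5, seed=1)
        S_arbitrary = rng.random((10, 4))
        fixed = nmf_fixed_weightings(X, S_arbitrary, seed=1)
        assert fixed.vaf_overall <= free.vaf_overall + 0.01

    def test_all_ones_column_fits_constant_matrix(self):
        X = np.full((5, 30), 2.5)
        res = nmf_fixed_weightings(X, np.ones((5, 1)), seed=0)
        assert res.vaf_overall >= 0.999

    def test_fixed_activations_mirror(self, noiseless_cycle_set, model):
        X = averaged(noiseless_cycle_set, 40)
        P_true = model.activation_templates
        res = nmf_fixed_activations(X, P_true, seed=0)
        assert np.array_equal(res.P, P_true)
        assert res.vaf_overall >= 0.99
        assert np.all(np.diff(res.objective_trace) <= 1e-9)


class TestRandomBaseline:
    def test_deterministic_given_seed(self, cycle_set):
        X = averaged(cycle_set, 40)
        res = nmf(X, 5, restarts=5, seed=4)
        a = random_baseline(X, res, "random_P", seed=11)
        b = random_baseline(X, res, "random_P", seed=11)
        assert a.vaf == b.vaf

    def test_unoptimized_baseline_far_below_extraction(self, cycle_set):
        """Random factors leave a large VAF gap to the real factorization."""
        X = averaged(cycle_set, 40)
        res = nmf(X, 5, restarts=5, seed=4)
        for mode in ("random_P", "random_S"):
            gaps = [res.vaf_overall
                    - random_baseline(X, res, mode, seed=s).vaf
                    for s in range(20)]
            assert np.mean(gaps) >= 0.3

    def test_optimized_baseline_with_true_weightings_fits(self,
                                                          noiseless_cycle_set,
                                                          model):
        """Letting the 'random' activations converge under the update rules
        is equivalent to a fixed-weightings fit, so with the generating
        weightings it reaches near-perfect VAF."""
        X = averaged(noiseless_cycle_set, 40)
        peaks = (model.weightings @ model.activation_templates).max(
            axis=1, keepdims=True)
        res = nmf_fixed_weightings(X, model.weightings / peaks, seed=0)
        rep = random_baseline(X, res, "random_P", optimize=True, seed=5)
        assert rep.vaf >= 0.99
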