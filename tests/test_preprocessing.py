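"""Filtering, envelope, segmentation, time/peak normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import synergait as sg
from synergait.preprocessing import (zero_lag_butterworth, envelope,
                                     detect_cycles, time_normalize,
                                     peak_normalize)

FS = 2000.0


class TestZeroLagButterworth:
    def test_dc_gain_unity(self):
        x = np.full(4000, 3.7)
        y = zero_lag_butterworth(x, FS, "low", 10.0)
        assert np.allclose(y, x, rtol=1e-6)

    def test_stopband_attenuation(self):
        t = np.arange(8000) / FS
        x = np.sin(2 * np.pi * 100 * t)
        y = zero_lag_butterworth(x, FS, "low", 10.0)
        mid = slice(1000, 7000)  # avoid edge transients
        assert np.sqrt(np.mean(y[mid] ** 2)) < 0.01 * np.sqrt(np.mean(x[mid] ** 2))

    def test_zero_phase(self):
        t = np.arange(8000) / FS
        x = np.sin(2 * np.pi * 5 * t)
        y = zero_lag_butterworth(x, FS, "low", 10.0)
        lags = range(-20, 21)
        xc = [np.dot(np.roll(y, l), x) for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="1500"):
            zero_lag_butterworth(np.zeros(100), FS, "low", 1500.0)


class TestEnvelope:
    def test_zero_in_zero_out_and_nonnegative(self, rng):
        assert not np.any(envelope(np.zeros((3, 5000)), FS))
        x = rng.standard_normal((3, 5000))
        assert np.all(envelope(x, FS) >= 0)

    def test_positive_scaling_equivariance(self, rng):
        x = rng.standard_normal((2, 5000))
        assert np.allclose(envelope(7.0 * x, FS), 7.0 * envelope(x, FS),
                           atol=1e-10)

    def test_tracks_amplitude_modulation(self, rng):
        t = np.arange(0, 4, 1 / FS)
        mod = 1.0 + 0.8 * np.sin(2 * np.pi * 1.5 * t)
        carrier = rng.standard_normal(t.size)
        est = envelope((mod * carrier)[None], FS)[0]
        mid = slice(2000, 6000)
        assert np.corrcoef(est[mid], mod[mid])[0, 1] > 0.9

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            envelope(np.zeros((1, 3000)), fs=900.0)


class TestDetectCycles:
    def test_recovers_true_boundaries(self, subject):
        det = detect_cycles(subject.accel, subject.fs)
        truth = subject.true_boundaries
        assert len(det) == len(truth) == 41
        assert np.abs(det - truth).max() <= 0.010 * subject.fs

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError, match="insufficient step events"):
            detect_cycles(np.zeros(10000), FS)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_cycles(np.zeros(1000), FS)

    def test_count_invariant_under_cadence_jitter(self):
        base = sg.SimulationConfig(seed=17, cycle_duration_cv=0.0)
        jit = sg.SimulationConfig(seed=17, cycle_duration_cv=0.05)
        n = [len(detect_cycles(sg.generate_subject(c).accel, c.fs))
             for c in (base, jit)]
        assert n[0] == n[1] == 41

    def test_perfect_recall_and_precision_across_seeds(self):
        for seed in range(20):
            rec = sg.generate_subject(sg.SimulationConfig(seed=seed))
            det = detect_cycles(rec.accel, rec.fs)
            assert len(det) == len(rec.true_boundaries), f"seed {seed}"
            assert np.abs(det - rec.true_boundaries).max() <= 0.010 * rec.fs


class TestTimeNormalize:
    @pytest.mark.parametrize("n", [2, 57, 200, 2347])
    def test_output_is_200_points(self, n, rng):
        out = time_normalize(rng.random((3, n)))
        assert out.shape == (3, 200)

    def test_constant_channel_preserved(self):
        out = time_normalize(np.full((1, 123), 4.2))
        assert np.allclose(out, 4.2)

    def test_linear_ramp_exact(self):
        ramp = np.linspace(0, 1, 1000)[None]
        out = time_normalize(ramp)[0]
        assert out[0] == 0 and out[-1] == 1
        assert np.abs(out - np.linspace(0, 1, 200)).max() < 1e-9

    def test_idempotent_on_grid_input(self, rng):
        x = rng.random((4, 200))
        assert np.allclose(time_normalize(x), x, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            time_normalize(np.ones((2, 1)))


class TestPeakNormalize:
    def test_row_maxima_become_one(self, rng):
        X = rng.random((5, 50)) + 0.1
        out = peak_normalize(X)
        assert np.allclose(out.max(axis=1), 1.0)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, a):
        X = np.abs(np.sin(np.arange(40.0))).reshape(2, 20) + 0.01
        assert np.allclose(peak_normalize(a * X), peak_normalize(X))

    def test_zero_row_unchanged_with_warning(self, caplog):
        X = np.vstack([np.zeros(10), np.ones(10)])
        with caplog.at_level("WARNING"):
            out = peak_normalize(X)
        assert np.array_equal(out[0], np.zeros(10))
        assert any("all-zero" in r.message for r in caplog.records)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            peak_normalize(np.array([[-1.0, 2.0]]))


class TestPreprocessRecording:
    def test_shape_contract(self, cycle_set):
        assert cycle_set.cycles.shape == (40, 10, 200)
        assert np.all(cycle_set.cycles >= 0)

    def test_round_trip_against_ground_truth(self, noiseless_cycle_set,
                                             model):
        """Normalized cycles correlate with the generating envelopes."""
        truth = model.weightings @ model.activation_templates
        for c in (0, 20, 39):
            for m in range(10):
                r = np.corrcoef(noiseless_cycle_set.cycles[c, m],
                                truth[m])[0, 1]
                assert r > 0.95

    def test_true_boundaries_match_detected(self, subject):
        a = sg.preprocess_recording(subject, use_true_boundaries=True)
        b = sg.preprocess_recording(subject)
        # same impacts found, so the segmentations nearly coincide
        assert np.abs(a.boundaries - b.boundaries).max() <= 0.010 * subject.fs

    def test_insufficient_cycles_error_names_count(self, subject):
        with pytest.raises(ValueError, match="40"):
            sg.preprocess_recording(subject, n_cycles=99)
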