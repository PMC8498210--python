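"""COP preprocessing, sway metrics, and the stand-in balance score."""

import numpy as np
import pytest
from scipy import signal as sig

from fallsway import cop_signal

from conftest import make_trace


class TestPreprocess:
    def test_demean_constant_trace_is_zero(self):
        tr = make_trace(np.full(300, 4.2), np.full(300, -1.7))
        out = cop_signal.preprocess_trace(tr, demean=True)
        assert np.allclose(out.ml, 0) and np.allclose(out.ap, 0)

    def test_demean_is_translation_invariant(self, sim_trace):
        shifted = make_trace(sim_trace.ml + 12.5, sim_trace.ap - 3.0)
        a = cop_signal.preprocess_trace(sim_trace, demean=True)
        b = cop_signal.preprocess_trace(shifted, demean=True)
        np.testing.assert_allclose(a.ml, b.ml, atol=1e-9)
        np.testing.assert_allclose(a.ap, b.ap, atol=1e-9)

    def test_lowpass_variance_matches_spectral_oracle(self, rng):
        """Zero-phase 4th-order Butterworth on white noise: the output
        variance should match direct integration of the squared
        (forward+backward) power response over the flat input spectrum."""
        n, fs, cutoff = 60_000, 100.0, 10.0
        white = rng.standard_normal(n)
        tr = make_trace(white, rng.standard_normal(n), rate=fs)
        out = cop_signal.preprocess_trace(tr, demean=False, lowpass_cutoff_hz=cutoff)

        sos = sig.butter(4, cutoff, btype="low", fs=fs, output="sos")
        freqs, h = sig.sosfreqz(sos, worN=8192, fs=fs)
        # filtfilt power gain is |H|^4; white-noise spectrum is flat
        expected_ratio = np.trapezoid(np.abs(h) ** 4, freqs) / (fs / 2)
        observed_ratio = out.ml.var() / tr.ml.var()
        assert observed_ratio < 1.0
        assert observed_ratio == pytest.approx(expected_ratio, rel=0.05)

    def test_cutoff_at_or_above_nyquist_rejected(self, sim_trace):
        with pytest.raises(ValueError, match="[Nn]yquist|cutoff"):
            cop_signal.preprocess_trace(sim_trace, lowpass_cutoff_hz=50.0)

    def test_nonfinite_samples_rejected_at_construction(self):
        bad = np.zeros(100)
        bad[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            make_trace(bad, np.zeros(100))


class TestSwayFeatures:
    def test_constant_trace_has_zero_features(self):
        tr = make_trace(np.full(500, 2.0), np.full(500, 2.0))
        feats = cop_signal.compute_sway_features(tr)
        assert all(v == 0 for v in feats.as_dict().values())

    def test_sinusoid_path_length_is_four_amplitudes(self):
        # one full period of A*sin: total |increment| sums to 4A
        A, f, fs = 3.0, 1.0, 1000.0
        t = np.arange(int(fs / f) + 1) / fs     # closed period [0, 1/f]
        tr = make_trace(A * np.sin(2 * np.pi * f * t), np.zeros_like(t), rate=fs)
        feats = cop_signal.compute_sway_features(tr)
        assert feats.path_length_ml == pytest.approx(4 * A, rel=1e-3)

    def test_scale_equivariance_is_exact(self, sim_trace):
        c = 3.7
        scaled = make_trace(c * sim_trace.ml, c * sim_trace.ap)
        f1 = cop_signal.compute_sway_features(sim_trace).as_dict()
        f2 = cop_signal.compute_sway_features(scaled).as_dict()
        for key in f1:
            assert f2[key] == pytest.approx(c * f1[key], rel=1e-12), key

    def test_planar_path_dominates_and_velocity_identity(self, sim_trace):
        f = cop_signal.compute_sway_features(sim_trace)
        assert f.path_length_planar >= max(f.path_length_ml, f.path_length_ap)
        assert f.mean_velocity_planar == pytest.approx(
            f.path_length_planar / sim_trace.duration_s)

    def test_too_short_trace_names_jerk(self):
        tr = make_trace([0.0, 1.0], [0.0, 1.0], rate=2.0)
        with pytest.raises(ValueError, match="jerk"):
            cop_signal.compute_sway_features(tr)


class TestScoring:
    @pytest.mark.parametrize("score,category", [
        (1, "high"), (2, "high"), (3, "high"),
        (4, "moderate"), (5, "moderate"), (6, "moderate"),
        (7, "low"), (8, "low"), (10, "low"),
    ])
    def test_band_rule(self, score, category):
        assert cop_signal.categorize_score(score) == category

    @pytest.mark.parametrize("bad", [0, 11, -3, 5.5, "7"])
    def test_out_of_range_scores_rejected(self, bad):
        with pytest.raises(ValueError):
            cop_signal.categorize_score(bad)

    def _score_trace(self, trace, reference):
        clean = cop_signal.preprocess_trace(trace, demean=True)
        feats = cop_signal.compute_sway_features(clean)
        return cop_signal.score_balance(feats, None, reference)

    def test_extreme_indices_hit_score_extremes(self, linear_reference):
        quiet = make_trace(np.zeros(600), np.zeros(600))
        result = self._score_trace(quiet, linear_reference)
        assert result.score == 10 and result.category == "low"

        t = np.arange(600) / 100.0
        wild = make_trace(400 * np.sin(40 * t), 400 * np.cos(37 * t))
        result = self._score_trace(wild, linear_reference)
        assert result.score == 1 and result.category == "high"

    def test_amplified_sway_never_scores_higher(self, sim_trace, linear_reference):
        base = self._score_trace(sim_trace, linear_reference)
        for c in (1.5, 3.0, 10.0):
            scaled = make_trace(c * sim_trace.ml, c * sim_trace.ap)
            assert self._score_trace(scaled, linear_reference).score <= base.score

    def test_scoring_is_deterministic(self, sim_trace, linear_reference):
        a = self._score_trace(sim_trace, linear_reference)
        b = self._score_trace(sim_trace, linear_reference)
        assert a == b

    def test_missing_reference_feature_is_an_error(self, sim_trace, linear_reference):
        ref = cop_signal.ScoreReference(
            feature_names=("mean_velocity_planar", "neg_loglik_per_sample"),
            feature_means=np.zeros(2), feature_scales=np.ones(2),
            feature_weights=np.ones(2),
            decile_edges=np.arange(9, dtype=float),
        )
        feats = cop_signal.compute_sway_features(sim_trace)
        with pytest.raises(ValueError, match="neg_loglik_per_sample"):
            cop_signal.score_balance(feats, None, ref)

    def test_reference_json_round_trip(self, linear_reference):
        again = cop_signal.ScoreReference.from_json(linear_reference.to_json())
        np.testing.assert_array_equal(again.decile_edges,
                                      linear_reference.decile_edges)
        assert again.feature_names == linear_reference.feature_names

    def test_reference_validation(self):
        with pytest.raises(ValueError, match="decile"):
            cop_signal.ScoreReference(
                feature_names=("a",), feature_means=[0.0],
                feature_scales=[1.0], feature_weights=[1.0],
                decile_edges=np.zeros(9))
        with pytest.raises(ValueError, match="weights"):
            cop_signal.ScoreReference(
                feature_names=("a",), feature_means=[0.0],
                feature_scales=[1.0], feature_weights=[0.0],
                decile_edges=np.arange(9.0))
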