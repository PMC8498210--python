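"""Ground-truth properties of the stabilogram and cohort generators."""

import dataclasses

import numpy as np
import pytest

from fallsway import cop_signal, fall_epi, synthetic_data
from fallsway.synthetic_data import CohortSimConfig, SwaySimConfig


class TestSwayGenerator:
    def test_same_seed_is_bit_identical(self):
        cfg = SwaySimConfig(stability_level=0.5, seed=77)
        a = synthetic_data.simulate_cop_trace(cfg)
        b = synthetic_data.simulate_cop_trace(cfg)
        np.testing.assert_array_equal(a.ml, b.ml)
        np.testing.assert_array_equal(a.ap, b.ap)

    def test_lower_stability_means_more_sway(self):
        def mean_path(stability, n=30):
            total = 0.0
            for k in range(n):
                cfg = SwaySimConfig(stability_level=stability, seed=1000 + k)
                tr = synthetic_data.simulate_cop_trace(cfg)
                total += cop_signal.compute_sway_features(tr).path_length_planar
            return total / n

        paths = [mean_path(s) for s in (1.0, 0.5, 0.2)]
        assert paths[0] < paths[1] < paths[2]

    def test_strong_mean_reversion_pins_trace_near_zero(self):
        cfg = SwaySimConfig(stability_level=1.0, ou_mean_reversion=90.0,
                            base_noise_scale=1e-4, seed=3)
        tr = synthetic_data.simulate_cop_trace(cfg)
        feats = cop_signal.compute_sway_features(tr)
        assert np.abs(tr.ap).max() < 0.01
        assert feats.path_length_planar < 1.0

    def test_regime_chain_is_returned_on_request(self):
        cfg = SwaySimConfig(seed=5)
        trace, regimes = synthetic_data.simulate_cop_trace(cfg, return_regimes=True)
        assert regimes.shape == (trace.n_samples,)
        assert set(np.unique(regimes)) <= {0, 1, 2}

    def test_config_validation(self):
        with pytest.raises(ValueError, match="stability"):
            SwaySimConfig(stability_level=0.0)
        with pytest.raises(ValueError, match="regime_scales"):
            SwaySimConfig(n_regimes=2)


class TestCohortGenerator:
    def test_same_seed_reproduces_cohort(self):
        cfg = CohortSimConfig(n_participants=40, seed=9)
        a = synthetic_data.simulate_cohort(cfg)
        b = synthetic_data.simulate_cohort(cfg)
        assert a.participants == b.participants
        assert a.fall_log == b.fall_log
        assert a.score_histories == b.score_histories

    def test_zero_rate_means_zero_falls(self):
        cfg = CohortSimConfig(n_participants=50, lambda_retro=0.0,
                              syncope_event_prob=0.0, seed=2)
        cohort = synthetic_data.simulate_cohort(cfg)
        assert not cohort.fall_log

    def test_retrospective_counts_are_poisson_like(self):
        # uncapped 12-month recall counts: mean ~ lambda and mean ~ variance
        cfg = CohortSimConfig(n_participants=2000, lambda_retro=0.7,
                              max_one_prospective_fall=False, seed=4)
        cohort = synthetic_data.simulate_cohort(cfg, include_scores=False)
        counts = np.array([p.falls_retro_12m for p in cohort.participants])
        assert counts.mean() == pytest.approx(0.7, abs=0.06)
        assert counts.var() == pytest.approx(counts.mean(), rel=0.12)

    def test_six_month_recall_is_a_subset_of_twelve(self, small_cohort):
        for p in small_cohort.participants:
            assert 0 <= p.falls_retro_6m <= p.falls_retro_12m

    def test_cadence_sets_test_schedule(self, small_cohort):
        for p in small_cohort.participants:
            cadence = 30 if p.site == "SLF" else 60
            assert p.days_enrolled == (p.n_tests - 1) * cadence

    def test_single_fall_cap_limits_prospective_counts(self, small_cohort):
        for p in small_cohort.participants:
            assert len(p.counted_prospective_falls()) <= 1

    def test_scores_are_valid_and_start_at_enrollment(self, small_cohort):
        by_id = {p.id: p for p in small_cohort.participants}
        for h in small_cohort.score_histories:
            p = by_id[h.participant_id]
            assert h.entries[0][0] == p.first_test_date
            assert len(h.entries) == p.n_tests

    def test_ground_truth_reports_improver_assignment(self, small_cohort):
        truth = small_cohort.ground_truth
        assert truth.n_improvers <= truth.n_high_risk_baseline
        frac = truth.n_improvers / truth.n_high_risk_baseline
        assert frac == pytest.approx(truth.improving_fraction, abs=0.15)

    def test_end_to_end_rate_recovery_at_nominal_coverage(self):
        # a single 95% CI misses ~5% of the time, so check containment
        # frequency over replicate cohorts rather than one draw
        hits = 0
        for seed in range(20):
            cfg = CohortSimConfig(n_participants=400, rate_ratio=0.5,
                                  max_one_prospective_fall=False, seed=seed)
            cohort = synthetic_data.simulate_cohort(cfg, include_scores=False)
            report = fall_epi.analyze_cohort(cohort.participants)
            hits += report.falls.ci_low <= 0.5 <= report.falls.ci_high
        assert hits >= 16


class TestYamlConfig:
    def test_cohort_config_from_flat_yaml(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text(
            "n_participants: 80\nrate_ratio: 0.5\nimproving_fraction: 0.25\n")
        cfg = CohortSimConfig.from_yaml(path)
        assert cfg.n_participants == 80
        assert cfg.rate_ratio == 0.5
        assert cfg.lambda_retro == 0.70          # untouched default

    def test_sway_config_lists_become_tuples(self, tmp_path):
        path = tmp_path / "sway.yaml"
        path.write_text("n_regimes: 2\nregime_scales: [0.5, 2.0]\nseed: 3\n")
        cfg = SwaySimConfig.from_yaml(path)
        assert cfg.regime_scales == (0.5, 2.0)

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("n_participants: 10\nfall_rate: 0.7\n")
        with pytest.raises(ValueError, match="fall_rate"):
            CohortSimConfig.from_yaml(path)


class TestFixtures:
    def test_reference_ledger_margins(self):
        ledger = synthetic_data.reference_cohort_ledger()
        assert ledger.n == 53
        assert ledger.falls_retro == 37
        assert ledger.fallers_retro == 21
        assert ledger.falls_pros == ledger.fallers_pros == 7
        assert ledger.py_retro == 53.0
        assert ledger.py_pros == 38.61

    def test_matched_fixture_is_internally_consistent(self):
        parts = synthetic_data.matched_cohort_fixture()
        assert len(parts) == 21
        for p in parts:
            assert p.falls_retro_6m <= p.falls_retro_12m
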