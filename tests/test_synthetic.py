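"""Synthetic trial generator: calibration, determinism, invariants."""

import dataclasses

import numpy as np
import pytest

from painrct.config import (
    BehaviourConfig,
    ComplianceConfig,
    EEGSimConfig,
    StaiConfig,
    TrialConfig,
    VitalsConfig,
)
from painrct.epochs import CHANNELS
from painrct.errors import ConfigError, InvalidArgumentError
from painrct.nnrf import AlignConfig, nnrf_magnitude
from painrct.scores import detect_tachycardia, stai_state_score
from painrct.synthetic import (
    expected_compliance_rate,
    generate_cohort,
    generate_outcome_frame,
    generate_trial,
    is_compliant,
    simulate_behaviour,
    simulate_compliance,
    simulate_epoch,
    simulate_parent_stai,
    simulate_vitals,
)


class TestCohort:
    def test_eligibility_bounds(self):
        cohort = generate_cohort(112, 1)
        assert len(cohort) == 112
        assert all(p.gestational_age_at_birth >= 35 for p in cohort)
        assert all(0 <= p.postnatal_age <= 7 for p in cohort)
        assert all(
            p.postmenstrual_age == pytest.approx(p.gestational_age_at_birth + p.postnatal_age / 7)
            for p in cohort
        )

    def test_male_fraction_matches_calibration(self):
        cohort = generate_cohort(10000, 2)
        frac = np.mean([p.sex == "male" for p in cohort])
        assert 0.59 <= frac <= 0.63

    def test_seeded_determinism(self):
        assert generate_cohort(5, 3) == generate_cohort(5, 3)

    def test_invalid_n_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_cohort(0, 1)


class TestEpochSimulation:
    def test_null_magnitude_scores_near_zero(self, template):
        scores = [
            nnrf_magnitude(
                simulate_epoch(None, 0.0, EEGSimConfig(), seed=s, template=template),
                template,
                AlignConfig(0.0),
                check_artefact=False,
            ).magnitude
            for s in range(50)
        ]
        assert abs(np.mean(scores)) < 0.1

    def test_noiseless_identity(self, template):
        cfg = EEGSimConfig(noise_rms_uv=0.0, latency_jitter_sd_ms=0.0)
        ep = simulate_epoch(None, 1.0, cfg, seed=0, template=template)
        expected = template.sampled_at(ep.times)
        assert np.allclose(ep.channel("Cz"), expected, atol=1e-12)
        # neighbouring channels carry the attenuated copy
        assert np.allclose(ep.channel("C3"), 0.5 * expected, atol=1e-12)

    def test_jitter_escaping_epoch_rejected(self, template):
        cfg = EEGSimConfig(epoch_window=(-0.5, 0.72), latency_jitter_max_ms=50.0)
        with pytest.raises(ConfigError):
            simulate_epoch(None, 1.0, cfg, seed=0, template=template)


class TestVitals:
    def test_zero_surge_never_tachycardic(self):
        cfg = VitalsConfig(fixed_surge_amplitude=0.0)
        trace = simulate_vitals(None, None, cfg, seed=1)
        assert detect_tachycardia(trace) is False

    def test_large_surge_from_sub160_baseline_detected(self):
        cfg = VitalsConfig(baseline_hr_mean=130.0, baseline_hr_sd=0.0, fixed_surge_amplitude=40.0)
        trace = simulate_vitals(None, None, cfg, seed=1)
        assert detect_tachycardia(trace) is True

    def test_crossing_probability_calibrated(self):
        cfg = VitalsConfig(p_cross=0.10)
        rng = np.random.default_rng(5)
        hits = sum(detect_tachycardia(simulate_vitals(None, None, cfg, rng)) for _ in range(2000))
        assert 0.08 <= hits / 2000 <= 0.12

    def test_trace_invariants(self):
        trace = simulate_vitals(None, None, VitalsConfig(), seed=9)
        assert np.all(np.diff(trace.time) > 0)
        assert np.all(trace.heart_rate > 0)
        assert np.all((trace.spo2 >= 0) & (trace.spo2 <= 100))


class TestBehaviour:
    def test_zero_magnitude_zero_noise_gives_zero_durations(self):
        fa = simulate_behaviour(None, 0.0, BehaviourConfig(noise_sd=0.0), seed=1)
        assert fa.brow_bulge_duration == fa.eye_squeeze_duration == 0.0
        assert fa.nasolabial_furrow_duration == 0.0

    def test_durations_monotone_in_magnitude(self):
        rng = np.random.default_rng(2)
        lo = [simulate_behaviour(None, 0.5, None, rng).brow_bulge_duration for _ in range(1000)]
        hi = [simulate_behaviour(None, 2.0, None, rng).brow_bulge_duration for _ in range(1000)]
        assert np.mean(hi) > np.mean(lo)

    def test_durations_clipped_to_window(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            fa = simulate_behaviour(None, 10.0, None, rng)
            assert 0 <= fa.brow_bulge_duration <= 30.0


class TestCompliance:
    def test_control_always_compliant_after_30s(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            rec = simulate_compliance("control", None, rng)
            assert rec.compliant and rec.stroke_start >= 30.0
            assert rec.stroke_end - rec.stroke_start == pytest.approx(10.0)

    def test_45s_rule_boundaries(self):
        assert is_compliant("intervention", 50.0) is False
        assert is_compliant("intervention", 45.0) is True  # 'more than 45 s' rule
        assert is_compliant("intervention", 10.0) is True
        assert is_compliant("control", float("nan")) is True

    def test_delay_distribution_calibration(self):
        cfg = ComplianceConfig()
        rng = np.random.default_rng(6)
        delays = np.array(
            [simulate_compliance("intervention", cfg, rng).delay_to_lance for _ in range(5000)]
        )
        assert np.median(delays) == pytest.approx(17.0, rel=0.1)
        noncomp = np.mean(delays > 45.0)
        assert 0.05 < noncomp < 0.20

    def test_target_rate_solves_sigma_exactly(self):
        cfg = ComplianceConfig(target_rate=0.85)
        assert expected_compliance_rate(cfg) == pytest.approx(0.85, abs=1e-12)
        rng = np.random.default_rng(7)
        comp = np.mean(
            [simulate_compliance("intervention", cfg, rng).compliant for _ in range(5000)]
        )
        assert 0.82 < comp < 0.88


class TestStai:
    def test_totals_bounded_by_item_range(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            sheets = simulate_parent_stai(generate_cohort(1, rng)[0], None, rng)
            for s in sheets:
                assert 20 <= stai_state_score(s) <= 80

    def test_mean_post_total_near_configured_mean(self):
        rng = np.random.default_rng(9)
        cohort = generate_cohort(1000, rng)
        totals = [
            stai_state_score(simulate_parent_stai(p, StaiConfig(post_state_mean=35.0), rng)[2])
            for p in cohort
        ]
        assert 33 <= np.mean(totals) <= 37

    def test_zero_variance_gives_identical_totals(self):
        rng = np.random.default_rng(10)
        cfg = StaiConfig(latent_scale=0.0, noise_sd=0.0)
        cohort = generate_cohort(10, rng)
        totals = {stai_state_score(simulate_parent_stai(p, cfg, rng)[2]) for p in cohort}
        assert len(totals) == 1


class TestGenerateTrial:
    def test_null_effect_keeps_arms_exchangeable(self):
        cfg = TrialConfig(seed=12, n=112)
        cfg = cfg.replace(ground_truth=dataclasses.replace(cfg.ground_truth, complier_effect_r=0.0))
        frame = generate_outcome_frame(cfg)
        means = frame.groupby("arm").true_magnitude.mean()
        assert abs(means["intervention"] - means["control"]) < 0.2

    def test_minimisation_keeps_arms_near_balance(self):
        frame = generate_outcome_frame(TrialConfig(seed=13, n=112))
        counts = frame.arm.value_counts()
        assert 52 <= counts["intervention"] <= 60
        assert 52 <= counts["control"] <= 60

    def test_multiplicative_effect_by_construction(self):
        cfg = TrialConfig(seed=14, n=4000)
        cfg = cfg.replace(
            ground_truth=dataclasses.replace(cfg.ground_truth, complier_effect_r=0.4),
            compliance=dataclasses.replace(cfg.compliance, threshold_s=1e9),  # full compliance
        )
        frame = generate_outcome_frame(cfg)
        means = frame.groupby("arm").true_magnitude.mean()
        assert means["intervention"] / means["control"] == pytest.approx(0.6, abs=0.05)

    def test_full_dataset_determinism_and_invariants(self, template):
        cfg = TrialConfig(seed=15, n=6)
        d1, d2 = generate_trial(cfg), generate_trial(cfg)
        assert d1.participants == d2.participants
        assert d1.allocations.equals(d2.allocations)
        assert d1.ground_truth.true_magnitudes == d2.ground_truth.true_magnitudes
        for pid in d1.epochs:
            for ev in ("lance", "sham"):
                assert np.array_equal(d1.epochs[pid][ev].data, d2.epochs[pid][ev].data)
        # per-type invariants are enforced by the record constructors on access
        for pid, tr in d1.vitals.items():
            assert np.all((tr.spo2 >= 0) & (tr.spo2 <= 100))
        assert set(d1.epochs) == {p.id for p in d1.participants}
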