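"""Simulator contracts: determinism, marginals, outcome models, calibration."""

from __future__ import annotations

import math

import numpy as np
import pytest
from pydantic import ValidationError
from scipy.special import expit, logit

from adhocscore.records import record_equal, validate_record
from adhocscore.simulate import (
    ScoreTableModel,
    SimulationConfig,
    calibrate_intercept,
    generate_cohort,
    generate_cohort_with_truth,
)


def zero_loading_config(**kw) -> SimulationConfig:
    return SimulationConfig(default_loading=0.0, **kw)


class TestDeterminismAndShape:
    def test_empty_cohort(self):
        assert generate_cohort(SimulationConfig(n=0, seed=1)) == []

    def test_same_config_same_cohort(self):
        cfg = SimulationConfig(n=300, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(SimulationConfig(n=300, seed=42))
        assert all(record_equal(x, y) for x, y in zip(a, b))

    def test_growing_n_preserves_earlier_records(self):
        """Per-variable substreams are consumed in record order, so the first
        k records are invariant to the cohort size."""
        small = generate_cohort(SimulationConfig(n=200, seed=9))
        big = generate_cohort(SimulationConfig(n=700, seed=9))
        for x, y in zip(small, big[:200]):
            assert record_equal(x, y)

    def test_different_seeds_differ(self):
        a = generate_cohort(SimulationConfig(n=100, seed=1))
        b = generate_cohort(SimulationConfig(n=100, seed=2))
        assert not all(record_equal(x, y) for x, y in zip(a, b))

    def test_generated_records_are_valid(self):
        cfg = SimulationConfig(n=1000, seed=3, missingness={"gcs": 0.3, "hb": 0.2})
        for rec in generate_cohort(cfg):
            errors = [i for i in validate_record(rec) if i.severity == "error"]
            assert errors == []


class TestMarginals:
    def test_indicator_prevalences_match_configuration(self):
        """With zero factor loadings each indicator is an independent
        Bernoulli draw; sample prevalence must sit within 3 binomial SEs."""
        n = 50_000
        recs, truth = generate_cohort_with_truth(zero_loading_config(n=n, seed=101))
        m = SimulationConfig().marginals
        observed = {
            "male": np.mean([r.sex == "male" for r in recs]),
            "blunt": np.mean([r.mechanism == "blunt" for r in recs]),
            "gcs_lt_12": np.mean([r.gcs < 12 for r in recs]),
            "sbp_le_90": np.mean([r.sbp <= 90 for r in recs]),
            "inr_gt_1_4": np.mean([r.inr > 1.4 for r in recs]),
            "hb_lt_7": np.mean([r.hb < 7 for r in recs]),
            "hemothorax": np.mean([r.hemothorax for r in recs]),
            "be_le_minus6": np.mean([r.base_excess <= -6 for r in recs]),
            "intubated": np.mean([r.intubated for r in recs]),
        }
        for name, p_hat in observed.items():
            p = getattr(m, name)
            se = math.sqrt(p * (1 - p) / n)
            assert abs(p_hat - p) <= 3 * se, name

    def test_horowitz_conditional_prevalence(self):
        recs = generate_cohort(zero_loading_config(n=50_000, seed=102))
        intubated = [r for r in recs if r.intubated]
        p = SimulationConfig().marginals.pf_le_200
        p_hat = np.mean([r.pao2_fio2 <= 200 for r in intubated])
        se = math.sqrt(p * (1 - p) / len(intubated))
        assert abs(p_hat - p) <= 3 * se
        assert all(r.pao2_fio2 is None for r in recs if not r.intubated)

    def test_every_patient_has_a_major_fracture(self):
        recs = generate_cohort(SimulationConfig(n=2000, seed=4))
        assert all(r.fracture_pelvis or r.fracture_femur or r.fracture_tibia for r in recs)

    def test_age_bounds_and_location(self):
        from scipy import stats

        cfg = SimulationConfig(n=20_000, seed=5)
        recs = generate_cohort(cfg)
        ages = np.array([r.age for r in recs])
        assert ages.min() >= 16 and ages.max() <= 100
        am = cfg.age_model
        a, b = (am.lower - am.mean) / am.sd, (am.upper - am.mean) / am.sd
        expected = stats.truncnorm.mean(a, b, loc=am.mean, scale=am.sd) - 0.5  # floor to int
        assert abs(ages.mean() - expected) < 0.5

    def test_continuous_values_consistent_with_own_threshold(self):
        """The conditional draw guarantees indicator/value agreement, so the
        truth sidecar's aspects equal a re-score of the records."""
        from adhocscore.adhoc import adhoc_score

        recs, truth = generate_cohort_with_truth(SimulationConfig(n=3000, seed=6))
        rescored = [adhoc_score(r).score for r in recs]
        assert rescored == truth["true_score"].tolist()


class TestDependence:
    def test_loading_increases_indicator_correlation(self):
        """The latent severity factor couples indicators: pairwise sample
        correlation is non-decreasing across three loading levels."""
        pairs = [("gcs_lt_12", "sbp_le_90"), ("be_le_minus6", "inr_gt_1_4"),
                 ("hemothorax", "hb_lt_7")]
        cors = []
        for lam in (0.0, 0.4, 0.8):
            _, truth = generate_cohort_with_truth(
                SimulationConfig(n=30_000, seed=77, default_loading=lam))
            recs = generate_cohort(SimulationConfig(n=30_000, seed=77, default_loading=lam))
            ind = {
                "gcs_lt_12": np.array([r.gcs < 12 for r in recs]),
                "sbp_le_90": np.array([r.sbp <= 90 for r in recs]),
                "be_le_minus6": np.array([r.base_excess <= -6 for r in recs]),
                "inr_gt_1_4": np.array([r.inr > 1.4 for r in recs]),
                "hemothorax": np.array([r.hemothorax for r in recs]),
                "hb_lt_7": np.array([r.hb < 7 for r in recs]),
            }
            cors.append([np.corrcoef(ind[a], ind[b])[0, 1] for a, b in pairs])
        for i in range(len(pairs)):
            assert cors[0][i] <= cors[1][i] + 0.02
            assert cors[1][i] <= cors[2][i] + 0.02


class TestOutcomes:
    def test_score_table_mode_hits_per_score_mortality(self):
        cfg = SimulationConfig(n=50_000, seed=11)
        cfg = cfg.model_copy(update={"mortality": cfg.mortality.model_copy(
            update={"mode": "score_table"})})
        recs, truth = generate_cohort_with_truth(cfg)
        table = cfg.mortality.score_table.probs
        scores = truth["true_score"].to_numpy()
        died = np.array([r.died for r in recs])
        for k in range(5):
            sel = scores == k
            n_k = int(sel.sum())
            assert n_k > 30
            p = table[k]
            se = math.sqrt(p * (1 - p) / n_k)
            assert abs(died[sel].mean() - p) <= 3 * se + 1e-12, k

    def test_mof_score_table_defaults(self):
        recs, truth = generate_cohort_with_truth(SimulationConfig(n=50_000, seed=12))
        probs = SimulationConfig().mof.score_table.probs
        scores = truth["true_score"].to_numpy()
        mof = np.array([r.mof for r in recs])
        for k in range(5):
            sel = scores == k
            p = probs[k]
            se = math.sqrt(p * (1 - p) / sel.sum())
            assert abs(mof[sel].mean() - p) <= 3 * se

    def test_los_means_track_score(self):
        cfg = SimulationConfig(n=60_000, seed=13)
        recs, truth = generate_cohort_with_truth(cfg)
        scores = truth["true_score"].to_numpy()
        icu = np.array([r.icu_los for r in recs])
        for k in range(3):  # strata 0..2 are large enough for a tight mean
            sel = scores == k
            assert abs(icu[sel].mean() - cfg.los.icu_means[k]) < 0.75


class TestCalibration:
    def test_closed_form_when_coefficients_are_null(self):
        cfg = SimulationConfig(n=100, seed=1)
        cfg.mortality.aspect_logistic.or_age = 1.0
        cfg.mortality.aspect_logistic.or_head = 1.0
        cfg.mortality.aspect_logistic.or_oxygenation = 1.0
        cfg.mortality.aspect_logistic.or_circulation = 1.0
        c = calibrate_intercept(cfg, n_calibration=10_000)
        assert abs(expit(c) - 0.119) <= 1e-3
        assert abs(c - logit(0.119)) < 0.02

    def test_calibrated_cohort_hits_target_mortality(self):
        recs = generate_cohort(SimulationConfig(n=100_000, seed=7))
        assert abs(np.mean([r.died for r in recs]) - 0.119) <= 0.005

    def test_unattainable_target_raises(self):
        cfg = SimulationConfig(n=100, seed=1)
        with pytest.raises(ValueError, match="unattainable"):
            calibrate_intercept(cfg, target_mortality=0.0, n_calibration=5_000)

    def test_wrong_mode_raises(self):
        cfg = SimulationConfig(n=100, seed=1)
        cfg = cfg.model_copy(update={"mortality": cfg.mortality.model_copy(
            update={"mode": "score_table"})})
        with pytest.raises(ValueError, match="aspect_logistic"):
            calibrate_intercept(cfg)


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValidationError):
            SimulationConfig(marginals={"male": 1.2})

    def test_unknown_loading_key(self):
        with pytest.raises(ValidationError, match="unknown indicator"):
            SimulationConfig(loadings={"nonexistent": 0.5})

    def test_missingness_field_names_checked(self):
        with pytest.raises(ValidationError, match="unknown field"):
            SimulationConfig(missingness={"heart_rate": 0.1})

    def test_score_table_shape_and_monotonicity(self):
        with pytest.raises(ValidationError):
            ScoreTableModel(probs=[0.1, 0.2, 0.3])
        with pytest.raises(ValidationError, match="monotone"):
            ScoreTableModel(probs=[0.3, 0.2, 0.3, 0.4, 0.5])
        ScoreTableModel(probs=[0.3, 0.2, 0.3, 0.4, 0.5], monotone=False)
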