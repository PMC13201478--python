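"""Synthetic-data generators: determinism, calibration, recovery."""

import numpy as np
import pandas as pd
import pytest

from rvometals.cohort import build_analysis_cohort
from rvometals.exposure import SingleMetalLogit, continuous_or
from rvometals.simulate import (
    CohortSimConfig,
    ExpressionSimConfig,
    simulate_cohort,
    simulate_expression,
    simulate_qpcr,
)
from rvometals.transcriptomics import ddct_fold_change, screen_candidates

from .conftest import NULL_COVARIATES


class TestDeterminism:
    def test_cohort_byte_identical(self):
        cfg = CohortSimConfig(n_participants=500, seed=3)
        a, ta = simulate_cohort(cfg)
        b, tb = simulate_cohort(CohortSimConfig(n_participants=500, seed=3))
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta.table, tb.table)
        assert a.to_csv() == b.to_csv()

    def test_expression_reproducible(self):
        cfg = ExpressionSimConfig(n_genes=100, seed=8)
        a, la = simulate_expression(cfg)
        b, lb = simulate_expression(ExpressionSimConfig(n_genes=100, seed=8))
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_series_equal(la, lb)

    def test_qpcr_reproducible(self):
        a = simulate_qpcr(4, 2.0, 0.2, seed=5)
        b = simulate_qpcr(4, 2.0, 0.2, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a, _ = simulate_cohort(CohortSimConfig(n_participants=200, seed=1))
        b, _ = simulate_cohort(CohortSimConfig(n_participants=200, seed=2))
        assert not a.equals(b)


class TestConfigValidation:
    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortSimConfig(n_participants=0).validate()
        with pytest.raises(ValueError):
            CohortSimConfig(outcome_prevalence_target=1.5).validate()
        bad_corr = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="semidefinite"):
            CohortSimConfig(metal_correlation=bad_corr).validate()
        with pytest.raises(ValueError):
            CohortSimConfig(missing_rates={"metals": 1.0}).validate()
        with pytest.raises(ValueError):
            ExpressionSimConfig(frac_monotone_down=0.7, frac_monotone_up=0.6).validate()

    def test_unreachable_prevalence_errors(self):
        cfg = CohortSimConfig(
            n_participants=200,
            outcome_prevalence_target=1e-9,
            covariate_effects={"age": 50.0},  # eta so large bisection cannot reach
        )
        with pytest.raises(ValueError, match="unreachable"):
            simulate_cohort(cfg)


class TestInterceptCalibration:
    def test_prevalence_within_ten_percent_relative(self):
        """At n = 200,000 the realized latent prevalence lands within
        +/-10% relative of the 0.006 target (all metal effects null)."""
        cfg = CohortSimConfig(
            n_participants=200000,
            seed=17,
            beta_log10_pb=0.0,
            beta_log10_cd=0.0,
            beta_log10_hg=0.0,
            outcome_prevalence_target=0.006,
            missing_rates={},
        )
        _, truth = simulate_cohort(cfg)
        prev = truth.table["outcome"].mean()
        assert abs(prev - 0.006) / 0.006 < 0.10


class TestEffectRecovery:
    def test_null_lead_or_ci_coverage(self):
        """beta_log10_pb = 0: the univariable CI covers OR = 1 at close to
        the nominal rate (>= 90/100 pre-registered seeds; a ~3.7-sigma
        binomial lower bound at 95% coverage)."""
        cover = 0
        for seed in range(100):
            raw, _ = simulate_cohort(
                CohortSimConfig(
                    n_participants=50000, seed=seed, beta_log10_pb=0.0,
                    missing_rates={},
                )
            )
            cohort, _ = build_analysis_cohort(raw)
            r = continuous_or(cohort, "pb")
            cover += r.ci_low <= 1 <= r.ci_high
        assert cover >= 90

    def test_lead_effect_within_3se(self):
        """beta_log10_pb = 0.8 at n = 50,000: the estimated log OR falls
        within 3 SE of 0.8 in >= 95/100 replicates."""
        ok = 0
        for seed in range(100):
            raw, _ = simulate_cohort(
                CohortSimConfig(
                    n_participants=50000, seed=seed, beta_log10_pb=0.8,
                    covariate_effects=NULL_COVARIATES, missing_rates={},
                )
            )
            cohort, _ = build_analysis_cohort(raw)
            res = SingleMetalLogit(cohort, "pb").fit()
            ok += abs(res.fit.params[1] - 0.8) <= 3 * res.fit.bse[1]
        assert ok >= 95


class TestExpression:
    def test_noiseless_all_down_strictly_decreasing(self):
        counts, labels = simulate_expression(
            ExpressionSimConfig(
                n_genes=200, frac_monotone_down=1.0, frac_monotone_up=0.0,
                noise_cv=0.0, seed=1,
            )
        )
        assert (labels == "down").all()
        arr = counts.to_numpy()
        assert np.all(arr[:, 0] > arr[:, 1]) and np.all(arr[:, 1] > arr[:, 2])

    def test_no_designated_monotone_genes_noiseless_passes_zero(self):
        """With no designated monotone genes and no noise, flat triples are
        exactly tied, so the strict filter passes nothing."""
        counts, _ = simulate_expression(
            ExpressionSimConfig(
                n_genes=500, frac_monotone_down=0.0, frac_monotone_up=0.0,
                noise_cv=0.0, seed=2,
            )
        )
        cands = screen_candidates(counts, eye_genes=set(counts.index))
        assert all(c.monotone_direction == "none" for c in cands)

    def test_flat_genes_monotone_at_exchangeable_rate_under_noise(self):
        """Independent noise on a flat triple orders it strictly monotone
        (either direction) with probability exactly 1/3 by exchangeability —
        noise magnitude is irrelevant; only ties (zero noise) prevent it."""
        counts, _ = simulate_expression(
            ExpressionSimConfig(
                n_genes=2000, frac_monotone_down=0.0, frac_monotone_up=0.0,
                noise_cv=0.01, seed=2,
            )
        )
        cands = screen_candidates(counts, eye_genes=set(counts.index))
        frac = np.mean([c.monotone_direction != "none" for c in cands])
        assert frac == pytest.approx(1 / 3, abs=0.04)

    def test_truth_labels_match_directions_noiseless(self):
        counts, labels = simulate_expression(
            ExpressionSimConfig(
                n_genes=300, frac_monotone_down=0.3, frac_monotone_up=0.2,
                noise_cv=0.0, seed=3,
            )
        )
        cands = {c.gene: c for c in screen_candidates(counts, set(counts.index))}
        for gene, cls in labels.items():
            expected = {"down": "decreasing", "up": "increasing", "flat": "none"}[cls]
            assert cands[gene].monotone_direction == expected


class TestQPCR:
    @pytest.mark.parametrize("fold", [1.0, 2.0, 0.5])
    def test_noiseless_fold_exact(self, fold):
        ct = simulate_qpcr(3, fold, ct_noise_sd=0.0, seed=0)
        res = ddct_fold_change(ct, "TARGET")
        assert res.fold_change == pytest.approx(fold)

    def test_noisy_fold_recovery_rate(self):
        """fold 0.5, Ct noise 0.1, n = 6: recovered fold in [0.4, 0.6] in
        >= 90% of 200 seeds."""
        ok = 0
        for seed in range(200):
            ct = simulate_qpcr(6, 0.5, ct_noise_sd=0.1, seed=seed)
            res = ddct_fold_change(ct, "TARGET")
            ok += 0.4 <= res.fold_change <= 0.6
        assert ok >= 180
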