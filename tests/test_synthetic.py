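"""Synthetic cohort generator: reproducibility, prevalence control,
missingness mechanisms and the generative-model oracle."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from gaoof import (
    CONTINUOUS_FEATURES,
    Cohort,
    ConfigurationError,
    SyntheticConfig,
    auc,
    generate_cohort,
    inject_missingness,
    oracle_auc,
)
from gaoof.synthetic import null_config


class TestConfigValidation:
    def test_non_psd_correlation_rejected(self):
        C = np.eye(13)
        C[0, 1] = C[1, 0] = 1.5  # eigenvalue < 0
        with pytest.raises(ConfigurationError, match="positive semi-definite"):
            SyntheticConfig(n_participants=10, correlation_matrix=C)

    def test_asymmetric_correlation_rejected(self):
        C = np.eye(13)
        C[0, 1] = 0.5
        with pytest.raises(ConfigurationError, match="symmetric"):
            SyntheticConfig(n_participants=10, correlation_matrix=C)

    @pytest.mark.parametrize("field,value", [
        ("target_prevalence", 0.0),
        ("target_prevalence", 1.0),
        ("mcar_rate", -0.1),
        ("mcar_rate", 1.0),
        ("hba1c_structural_missing_fraction", 1.0),
        ("grade_e_fraction", -0.01),
    ])
    def test_fraction_ranges(self, field, value):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(n_participants=10, **{field: value})

    def test_weight_length_must_match_feature_count(self):
        with pytest.raises(ConfigurationError, match="true_weights"):
            SyntheticConfig(n_participants=10, true_weights=np.zeros(5))

    def test_unreachable_prevalence_raises_convergence_error(self):
        from gaoof import ConvergenceError

        cfg = SyntheticConfig(n_participants=100, seed=0)
        cfg.true_weights = np.full(21, np.inf)  # bypass validation deliberately
        with np.errstate(invalid="ignore"), pytest.raises(
            (ConvergenceError, ConfigurationError)
        ):
            generate_cohort(cfg)


class TestGenerateCohort:
    def test_bit_identical_given_seed(self):
        cfg = SyntheticConfig(n_participants=500, seed=123)
        a = generate_cohort(cfg).data
        b = generate_cohort(SyntheticConfig(n_participants=500, seed=123)).data
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = generate_cohort(SyntheticConfig(n_participants=500, seed=1)).data
        b = generate_cohort(SyntheticConfig(n_participants=500, seed=2)).data
        assert not a["fpg"].equals(b["fpg"])

    def test_null_weights_prevalence_and_independence(self):
        # zero weights: realized prevalence near target, outcome carries no signal
        cfg = null_config(8000, seed=11, target_prevalence=0.375)
        cohort = generate_cohort(cfg)
        y = cohort.labels()
        se = np.sqrt(0.375 * 0.625 / len(y))
        assert abs(y.mean() - 0.375) < 3 * se
        df = cohort.data.loc[cohort.data["outcome"].notna()]
        a = auc(df["fpg"].to_numpy(), df["outcome"].to_numpy().astype(int))
        assert abs(a - 0.5) < 3 / np.sqrt(len(df))

    def test_prevalence_control_over_replicates(self):
        # expectation of realized prevalence matches the target
        target = 0.375
        prevs = [
            generate_cohort(
                SyntheticConfig(n_participants=2000, seed=1000 + r)
            ).data["outcome"].mean()
            for r in range(200)
        ]
        assert abs(np.mean(prevs) - target) < 0.01

    def test_single_feature_auc_approaches_binormal_oracle(self):
        # one informative feature: empirical AUC of that feature converges to
        # the generative oracle computed by Monte-Carlo pairwise concordance
        w = np.zeros(21)
        w[CONTINUOUS_FEATURES.index("fpg")] = 1.5
        cfg = SyntheticConfig(
            n_participants=40000, seed=5, true_weights=w,
            correlation_matrix=np.eye(13),
        )
        oracle = oracle_auc(cfg, n_mc=200_000, seed=99)
        cohort = generate_cohort(cfg)
        df = cohort.data.loc[cohort.data["outcome"].notna()]
        emp = auc(df["fpg"].to_numpy(), df["outcome"].to_numpy().astype(int))
        assert abs(emp - oracle) < 0.01

    def test_grade_e_excluded_from_outcome(self):
        cfg = SyntheticConfig(n_participants=3000, seed=4, grade_e_fraction=0.1)
        cohort = generate_cohort(cfg)
        df = cohort.data
        assert df.loc[df["grade_e"], "outcome"].isna().all()
        assert df.loc[~df["grade_e"], "outcome"].notna().all()

    def test_clinical_ranges_plausible(self):
        cohort = generate_cohort(SyntheticConfig(n_participants=5000, seed=8))
        med = cohort.data[CONTINUOUS_FEATURES].median()
        assert 18 < med["bmi"] < 28
        assert 90 < med["sbp"] < 140
        assert 4.5 < med["hba1c"] < 6.5


class TestInjectMissingness:
    def test_zero_rates_identity(self, informative_cohort):
        cfg = dataclasses.replace(
            informative_cohort.config, mcar_rate=0.0,
            hba1c_structural_missing_fraction=0.0,
        )
        out = inject_missingness(informative_cohort, cfg)
        pd.testing.assert_frame_equal(out.data, informative_cohort.data)

    def test_mcar_rate_bounded(self):
        cfg = SyntheticConfig(n_participants=5000, seed=3, mcar_rate=0.02)
        out = inject_missingness(generate_cohort(cfg), cfg)
        se = np.sqrt(0.02 * 0.98 / 5000)
        for name in out.continuous_features:
            if name == "hba1c":
                continue
            assert out.data[name].isna().mean() <= 0.02 + 3 * se

    def test_structural_hba1c_fraction_and_policy_dependence(self):
        cfg = SyntheticConfig(
            n_participants=5000, seed=3, hba1c_structural_missing_fraction=0.3
        )
        out = inject_missingness(generate_cohort(cfg), cfg)
        miss = out.data["hba1c"].isna()
        assert abs(miss.mean() - 0.30) < 0.02
        # MNAR-by-policy: missingness is driven by the screening stratum
        table = pd.crosstab(miss, out.data["screening_stratum"])
        assert chi2_contingency(table).pvalue < 1e-10
        # and associated with the anchor covariate (lower-risk stratum untested)
        assert out.data.loc[miss, "fpg"].mean() < out.data.loc[~miss, "fpg"].mean()

    def test_outcome_never_masked(self, informative_cohort):
        out = inject_missingness(informative_cohort, informative_cohort.config)
        pd.testing.assert_series_equal(
            out.data["outcome"], informative_cohort.data["outcome"]
        )

    def test_deterministic_given_seed(self, informative_cohort):
        a = inject_missingness(informative_cohort, informative_cohort.config)
        b = inject_missingness(informative_cohort, informative_cohort.config)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestOracleAUC:
    def test_zero_weights_is_chance(self):
        assert abs(oracle_auc(null_config(100), n_mc=100_000, seed=1) - 0.5) < 0.01

    def test_refuses_small_mc(self):
        with pytest.raises(ConfigurationError):
            oracle_auc(null_config(100), n_mc=500)

    def test_matches_brute_force_pairwise_concordance(self):
        # independent O(n^2) oracle on the same generative draws
        from scipy.special import expit

        rng = np.random.default_rng(12)
        eta = 1.0 * rng.standard_normal(3000)
        from gaoof.synthetic import _calibrate_intercept

        c = _calibrate_intercept(eta, 0.375)
        y = (rng.random(3000) < expit(eta + c)).astype(int)
        pos, neg = eta[y == 1], eta[y == 0]
        brute = np.mean((pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :]))
        assert abs(auc(eta, y) - brute) < 1e-12

    def test_monotone_in_signal_strength(self):
        base = np.zeros(21)
        base[4] = 0.5
        last = 0.0
        for scale in (1.0, 2.0, 4.0):
            cfg = SyntheticConfig(
                n_participants=100, seed=0, true_weights=base * scale,
                correlation_matrix=np.eye(13),
            )
            a = oracle_auc(cfg, n_mc=150_000, seed=3)
            assert a > last
            last = a


class TestCohortIO:
    def test_csv_round_trip(self, tmp_path, informative_cohort):
        cfg = informative_cohort.config
        cohort = inject_missingness(informative_cohort, cfg)
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        back = Cohort.from_csv(path)
        assert back.config is not None
        assert back.config.seed == cfg.seed
        pd.testing.assert_series_equal(
            back.data["hba1c"], cohort.data["hba1c"], check_dtype=False
        )
        # empty cells parsed as missing markers, not zeros
        assert back.data["hba1c"].isna().sum() == cohort.data["hba1c"].isna().sum()
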