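"""The cleaning chain: filters, outliers, imputation, batch, residualization."""

import numpy as np
import pandas as pd
import pytest

from phenofuse import (CohortSpec, adjust_batch, clean_pipeline, corrupt_cohort,
                       filter_missing, generate_cohort, impute_median,
                       make_design, remove_outliers, residualize_on_controls,
                       zscore_patients)
from phenofuse.datatypes import ModalityTable
from phenofuse.synth import generate_controls

from conftest import table_from_array


class TestFilterMissing:
    def test_fully_missing_feature_dropped(self):
        X = np.ones((5, 5))
        X[:, 2] = np.nan
        out, rep = filter_missing(table_from_array(X, "m"))
        assert out.shape == (5, 4)
        assert rep.dropped_features["m"] == ["2"]
        assert rep.dropped_subjects == {}

    def test_threshold_is_inclusive_for_subjects(self):
        # a subject missing exactly 20% of the features is discarded (and
        # with 10 subjects the offending feature stays under its own 20%)
        X = np.ones((10, 5))
        X[0, 0] = np.nan
        out, rep = filter_missing(table_from_array(X))
        assert out.shape == (9, 5)
        assert rep.dropped_subjects == {"0": "missingness"}

    def test_crafted_pattern_counts(self):
        # 2 features at 30% missing dropped first; then 1 subject missing
        # 2 of the remaining 8 features (25%)
        X = np.ones((10, 10))
        X[:3, 0] = np.nan
        X[:3, 1] = np.nan
        X[9, 2] = np.nan
        X[9, 3] = np.nan
        out, rep = filter_missing(table_from_array(X, "m"))
        assert sorted(rep.dropped_features["m"]) == ["0", "1"]
        assert list(rep.dropped_subjects) == ["9"]
        assert out.shape == (9, 8)

    def test_feature_stage_runs_first(self):
        # subject 0 misses 40% overall, but both offenders are dropped
        # features, so the subject survives
        X = np.ones((5, 5))
        X[:, 0] = np.nan
        X[0, 1] = np.nan
        X[1:, 1] = np.nan
        out, _ = filter_missing(table_from_array(X))
        assert out.shape == (5, 3)

    def test_everything_dropped_names_stage(self):
        X = np.full((4, 3), np.nan)
        with pytest.raises(ValueError, match="feature-missingness"):
            filter_missing(table_from_array(X))


class TestRemoveOutliers:
    def test_homogeneous_table_untouched(self, rng):
        X = rng.normal(size=(30, 8))
        out, rep = remove_outliers(table_from_array(X), n_mads=10)
        assert out.shape == (30, 8)
        assert rep.dropped_subjects == {}

    def test_constructed_outlier_removed(self, rng):
        X = rng.normal(size=(25, 10))
        med = np.median(X, axis=0)
        mad = 1.4826 * np.median(np.abs(X - med), axis=0)
        X[3, :5] = med[:5] + 20 * mad[:5]
        out, rep = remove_outliers(table_from_array(X), n_mads=5)
        assert rep.dropped_subjects == {"3": "outlier"}
        assert out.shape == (24, 10)

    def test_identical_subjects_zero_mad(self):
        X = np.ones((3, 4))
        out, rep = remove_outliers(table_from_array(X), n_mads=5)
        assert out.shape == (3, 4)
        assert rep.dropped_subjects == {}

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            remove_outliers(table_from_array(np.ones((2, 3))))


class TestImputeMedian:
    def test_median_fill_value(self):
        X = np.array([[1.0], [2.0], [np.nan], [4.0]])
        out, rep = impute_median(table_from_array(X, "m"))
        assert out.values[2, 0] == pytest.approx(2.0)
        assert rep.imputed_cells["m"] == 1

    def test_no_missing_is_identity(self, rng):
        X = rng.normal(size=(6, 4))
        out, _ = impute_median(table_from_array(X))
        np.testing.assert_array_equal(out.values, X)

    def test_constant_column_fill(self):
        X = np.array([[7.0], [7.0], [np.nan]])
        out, _ = impute_median(table_from_array(X))
        assert out.values[2, 0] == 7.0

    def test_fully_missing_feature_rejected(self):
        X = np.array([[np.nan], [np.nan]])
        with pytest.raises(ValueError, match="no .* observed|observed"):
            impute_median(table_from_array(X))


class TestAdjustBatch:
    def test_additive_offset_equalized(self, rng):
        n, p = 60, 5
        X = rng.normal(size=(n, p))
        batch = np.repeat([0, 1], n // 2)
        X[batch == 1] += 5.0
        # raw location/scale removal equalizes per-batch means exactly
        out = adjust_batch(table_from_array(X), batch, shrink=False)
        means0 = out.values[batch == 0].mean(axis=0)
        means1 = out.values[batch == 1].mean(axis=0)
        np.testing.assert_allclose(means0, means1, atol=1e-6)
        # the empirical-Bayes default removes the shared +5 shift but keeps
        # (shrunken) per-feature deviations at the sampling-noise scale
        out_eb = adjust_batch(table_from_array(X), batch)
        gap = np.abs(out_eb.values[batch == 1].mean(0)
                     - out_eb.values[batch == 0].mean(0))
        assert gap.max() < 0.5

    def test_single_batch_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match=">= 2 batches"):
            adjust_batch(table_from_array(X), np.zeros(10, int))

    def test_singleton_batch_named(self, rng):
        X = rng.normal(size=(10, 3))
        batch = np.array([0] * 9 + [7])
        with pytest.raises(ValueError, match="7"):
            adjust_batch(table_from_array(X), batch)

    def test_null_batch_effect_near_identity(self, rng):
        X = rng.normal(size=(80, 6))
        batch = rng.integers(0, 2, size=80)
        out = adjust_batch(table_from_array(X), batch)
        # no real batch effect: the adjustment only removes (shrunken)
        # sampling-noise batch estimates, small relative to the unit noise
        assert np.abs(out.values - X).mean() < 0.2
        assert np.abs(out.values.mean(0) - X.mean(0)).max() < 0.15

    def test_covariate_variation_preserved(self, rng):
        n = 100
        age = rng.uniform(-1, 1, n)
        batch = rng.integers(0, 2, n)
        X = np.outer(age, np.full(4, 2.0)) + rng.normal(scale=0.3, size=(n, 4))
        X[batch == 1] += 3.0
        cov = pd.DataFrame({"age": age})
        out = adjust_batch(table_from_array(X), batch, cov)
        slope, intercept = np.polyfit(age, out.values[:, 0], 1)
        assert slope == pytest.approx(2.0, abs=0.3)
        # batch gap after accounting for the (protected) age effect
        resid = out.values.mean(1) - np.polyfit(
            age, out.values.mean(1), 1)[0] * age
        gap = resid[batch == 1].mean() - resid[batch == 0].mean()
        assert abs(gap) < 0.2


class TestResidualize:
    def _design(self, cov):
        return make_design(cov)

    def test_perfectly_explained_feature(self):
        ages = np.linspace(50, 70, 20)
        cov_p = pd.DataFrame({"age": ages, "sex": np.tile([0, 1], 10)})
        cov_c = pd.DataFrame({"age": ages + 1, "sex": np.tile([1, 0], 10)})
        Xp = (2 * cov_p["age"]).to_numpy()[:, None]
        Xc = (2 * cov_c["age"]).to_numpy()[:, None]
        out = residualize_on_controls(
            table_from_array(Xp), table_from_array(Xc),
            self._design(cov_p), self._design(cov_c))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-8)

    def test_covariate_free_feature_centered(self, rng):
        n = 200
        cov_p = pd.DataFrame({"age": rng.uniform(50, 70, n),
                              "sex": rng.integers(0, 2, n)})
        cov_c = pd.DataFrame({"age": rng.uniform(50, 70, n),
                              "sex": rng.integers(0, 2, n)})
        Xc = rng.normal(size=(n, 1))
        Xp = rng.normal(size=(n, 1))
        out = residualize_on_controls(
            table_from_array(Xp), table_from_array(Xc),
            self._design(cov_p), self._design(cov_c))
        # control covariates explain nothing: residual ~ Xp - control mean
        # up to the (noise-level) spurious slopes the control fit absorbs
        diff = out.values - (Xp - Xc.mean())
        assert np.sqrt((diff**2).mean()) < 0.25
        r = np.corrcoef(out.values.ravel(), (Xp - Xc.mean()).ravel())[0, 1]
        assert r > 0.97

    def test_disease_offset_survives(self, rng):
        n, delta = 150, 2.5
        cov_p = pd.DataFrame({"age": rng.uniform(50, 70, n),
                              "sex": rng.integers(0, 2, n)})
        cov_c = pd.DataFrame({"age": rng.uniform(50, 70, n),
                              "sex": rng.integers(0, 2, n)})
        beta = 0.1
        Xc = (beta * cov_c["age"]).to_numpy()[:, None] + rng.normal(
            scale=0.5, size=(n, 1))
        Xp = (beta * cov_p["age"]).to_numpy()[:, None] + delta + rng.normal(
            scale=0.5, size=(n, 1))
        out = residualize_on_controls(
            table_from_array(Xp), table_from_array(Xc),
            self._design(cov_p), self._design(cov_c))
        assert out.values.mean() == pytest.approx(delta, abs=0.3)

    def test_rank_deficient_design_rejected(self, rng):
        n = 30
        cov = pd.DataFrame({"age": np.full(n, 60.0), "sex": np.zeros(n)})
        X = rng.normal(size=(n, 2))
        with pytest.raises(ValueError, match="rank deficient"):
            residualize_on_controls(table_from_array(X), table_from_array(X),
                                    make_design(cov), make_design(cov))


class TestZscore:
    def test_exact_standardization(self):
        out = zscore_patients(table_from_array([[1.0], [2.0], [3.0]]))
        assert out.values.mean() == pytest.approx(0.0, abs=1e-15)
        assert out.values.std(ddof=1) == pytest.approx(1.0, abs=1e-15)

    def test_idempotent_on_standardized(self, rng):
        X = rng.normal(size=(50, 3))
        once = zscore_patients(table_from_array(X))
        twice = zscore_patients(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_constant_column_named(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="0"):
            zscore_patients(table_from_array(X))


class TestCleanPipelineEndToEnd:
    def test_repairs_corrupted_cohort(self):
        spec = CohortSpec(n_patients=200, n_controls=60, modality_dims=(12, 8),
                          n_clusters=2, cluster_sep=0.0, gradient_loading=0.0,
                          noise_sd=1.0, missing_rate=0.05, outlier_rate=0.02,
                          n_batches=2, batch_shift=1.0,
                          covariate_effects={"age": 0.05, "sex": 0.5,
                                             "age_sex": 0.0}, seed=21)
        tables, truth = generate_cohort(spec)
        corrupted = corrupt_cohort(tables, truth, spec)
        cleaned, report = clean_pipeline(
            corrupted, controls=generate_controls(truth),
            patient_covariates=truth.covariates,
            control_covariates=truth.control_covariates,
            batch=truth.batch)

        # every planted outlier is dropped (as an outlier, or earlier for
        # missingness if the MCAR mask happened to hit it hard)
        assert set(truth.outliers) <= set(report.dropped_subjects)
        assert any(r == "outlier" for r in report.dropped_subjects.values())

        survivors = cleaned[0].data.index
        keep = np.array([p in set(survivors) for p in tables[0].patients])
        batch = truth.batch[keep]
        age = truth.covariates.loc[survivors, "age"].to_numpy()
        for t in cleaned:
            X = t.values
            assert not np.isnan(X).any()
            # planted batch means equalized
            gap = np.abs(X[batch == 0].mean(0) - X[batch == 1].mean(0))
            assert gap.max() < 0.5
            # planted covariate slopes removed
            slopes = [np.polyfit(age, X[:, j], 1)[0] for j in range(X.shape[1])]
            assert np.abs(slopes).max() < 0.05
            # z-scored
            np.testing.assert_allclose(X.mean(0), 0.0, atol=1e-10)
            np.testing.assert_allclose(X.std(0, ddof=1), 1.0, atol=1e-10)
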