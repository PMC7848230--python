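"""Classifier enumeration, subsampling, filtration, extraction, training."""

import numpy as np
import pandas as pd
import pytest

from phenomark.ml import (
    ClassifierConfig,
    RFParams,
    StudyData,
    enumerate_configs,
    equalized_counts,
    extract_top_features,
    filter_phenotype_features,
    filter_taxonomic_features,
    mean_importances,
    subsample_equalize,
    train_and_evaluate,
    variant_importances,
)

#: quick forest for unit tests that exercise mechanics, not the
#: production hyperparameters
FAST_RF = RFParams(n_estimators=20)


class TestEnumerateConfigs:
    def test_three_datasets_give_28(self):
        configs = enumerate_configs(["CHN", "ESP", "NLD"])
        assert len(configs) == 28
        variants = {c.variant_key for c in configs}
        assert len(variants) == 7
        per_contrast = [c for c in configs if c.contrast == "CD"]
        assert len(per_contrast) == 14

    def test_one_dataset_gives_single_only(self):
        configs = enumerate_configs(["only"])
        assert len(configs) == 4
        assert {c.strategy for c in configs} == {"Single"}

    def test_two_datasets(self):
        configs = enumerate_configs(["a", "b"])
        assert len(configs) == 20  # (2 Single + 2 L1O + 1 Mixed) x 4

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_closed_form(self, n):
        configs = enumerate_configs([f"d{i}" for i in range(n)])
        assert len(configs) == (2 * n + 1) * 2 * 2

    def test_iteration_counts(self):
        configs = enumerate_configs(["a", "b", "c"])
        for c in configs:
            assert c.n_iterations == (3 if c.strategy == "L1O" else 10)


class TestSubsampling:
    def test_equalized_counts_take_minimum(self):
        counts = {
            "ESP": {"HC": 91, "CD": 34, "UC": 39},
            "NLD": {"HC": 496, "CD": 163, "UC": 99},
            "CHN": {"HC": 67, "CD": 50, "UC": 37},
        }
        assert equalized_counts(counts) == {"HC": 67, "CD": 34, "UC": 37}

    def test_equal_counts_noop(self):
        counts = {"a": {"UC": 37}, "b": {"UC": 37}, "c": {"UC": 37}}
        assert equalized_counts(counts) == {"UC": 37}

    def test_l1o_training_pair(self):
        counts = {"CHN": {"CD": 50}, "NLD": {"CD": 163}}
        assert equalized_counts(counts) == {"CD": 50}

    def test_sampled_ids_without_replacement(self, rng):
        ids = {
            "a": {"HC": [f"a{i}" for i in range(10)]},
            "b": {"HC": [f"b{i}" for i in range(4)]},
        }
        out = subsample_equalize(ids, rng)
        assert len(out["a"]["HC"]) == 4 and len(set(out["a"]["HC"])) == 4
        assert sorted(out["b"]["HC"]) == sorted(ids["b"]["HC"])
        assert set(out["a"]["HC"]) <= set(ids["a"]["HC"])


class TestTaxonomicFiltration:
    def table(self, col, n=20):
        t = pd.DataFrame({"keep": [0.05] * n, "probe": col})
        return t

    def test_too_few_nonzero_samples_dropped(self):
        col = [0.5] * 4 + [0.0] * 16
        assert "probe" not in filter_taxonomic_features([self.table(col)])

    def test_low_max_abundance_dropped(self):
        col = [0.009] * 20
        assert "probe" not in filter_taxonomic_features([self.table(col)])

    def test_passing_feature_retained(self):
        col = [0.05] * 20
        assert "probe" in filter_taxonomic_features([self.table(col)])

    def test_must_pass_in_every_dataset(self):
        good = self.table([0.05] * 20)
        bad = self.table([0.009] * 20)
        assert "probe" not in filter_taxonomic_features([good, bad])

    def test_idempotent_and_order_independent(self):
        a = self.table([0.05] * 20)
        b = self.table([0.02] * 4 + [0.0] * 16)
        assert filter_taxonomic_features([a, b]) == filter_taxonomic_features([b, a])
        kept = filter_taxonomic_features([a])
        assert filter_taxonomic_features([a[kept]]) == kept


class TestPhenotypeFiltration:
    def tables(self, cpi_col, pad_col, n=20):
        cpi = pd.DataFrame({"keep": [0.5] * n, "probe": cpi_col})
        pad = pd.DataFrame({"keep": [6.0] * n, "probe": pad_col})
        return [cpi], [pad]

    def test_extreme_mean_cpi_dropped(self):
        cpi, pad = self.tables([0.95] * 20, [6.0] * 20)
        assert "probe" not in filter_phenotype_features(cpi, pad)

    def test_low_mean_pad_dropped(self):
        cpi, pad = self.tables([0.5] * 20, [3.4] * 20)
        assert "probe" not in filter_phenotype_features(cpi, pad)

    def test_rarely_present_cpi_dropped(self):
        cpi, pad = self.tables([0.3] * 4 + [0.0] * 16, [6.0] * 20)
        # mean 0.06 also out of range; make mean pass but presence fail
        cpi[0]["probe"] = [0.6] * 4 + [0.04] * 16
        assert "probe" not in filter_phenotype_features(cpi, pad)

    def test_passing_phenotype_retained(self):
        cpi, pad = self.tables([0.5] * 20, [6.0] * 20)
        assert "probe" in filter_phenotype_features(cpi, pad)


class TestExtraction:
    def test_all_returned_when_k_exceeds_pool(self, rng):
        X = pd.DataFrame(rng.random((30, 10)),
                         columns=[f"f{i}" for i in range(10)])
        y = pd.Series(rng.integers(0, 2, 30))
        out = extract_top_features(X, y, FAST_RF, top_k=20, seed=0)
        assert out == sorted(X.columns)

    def test_separating_feature_selected(self, rng):
        n = 60
        y = pd.Series([0] * (n // 2) + [1] * (n // 2))
        X = pd.DataFrame(rng.random((n, 30)),
                         columns=[f"noise{i:02d}" for i in range(30)])
        X["signal"] = y * 2.0 + rng.random(n) * 0.01
        out = extract_top_features(X, y, FAST_RF, top_k=5, seed=0)
        assert "signal" in out

    def test_constant_features_tie_break_lexicographic(self):
        X = pd.DataFrame(0.0, index=range(30),
                         columns=[f"c{i:02d}" for i in range(25)])
        y = pd.Series([0, 1] * 15)
        out = extract_top_features(X, y, FAST_RF, top_k=5, seed=0)
        assert out == [f"c{i:02d}" for i in range(5)]


def two_cohort_study(rng, n_per=30, signal=3.0):
    """Two cohorts, one informative feature separating CD from HC."""
    features, labels = {}, {}
    for d in ("A", "B"):
        idx = [f"{d}{i}" for i in range(2 * n_per)]
        y = pd.Series(["HC"] * n_per + ["CD"] * n_per, index=idx)
        X = pd.DataFrame(
            rng.random((2 * n_per, 6)) * 0.2,
            index=idx,
            columns=[f"f{i}" for i in range(6)],
        )
        X["f0"] = X["f0"] + signal * (y == "CD").to_numpy()
        # scale into a range passing the taxonomic filter
        features[d] = X / 10.0
        labels[d] = y
    return StudyData(features={"taxonomy": features}, labels=labels)


class TestTrainAndEvaluate:
    def test_perfectly_separable_auc_one(self, rng):
        study = two_cohort_study(rng)
        config = ClassifierConfig("Single", "A", "taxonomy", "CD",
                                  rf=FAST_RF, n_iterations=2)
        results = train_and_evaluate(config, study, master_seed=1)
        assert all(r.auc == 1.0 for r in results)
        assert all(0 <= r.sensitivity <= 1 and 0 <= r.specificity <= 1
                   for r in results)

    def test_bit_reproducible_given_seed(self, rng):
        study = two_cohort_study(rng, signal=0.3)
        config = ClassifierConfig("Mixed", "all", "taxonomy", "CD",
                                  rf=FAST_RF, n_iterations=2)
        a = train_and_evaluate(config, study, master_seed=7)
        b = train_and_evaluate(config, study, master_seed=7)
        assert [r.auc for r in a] == [r.auc for r in b]
        for ra, rb in zip(a, b):
            pd.testing.assert_series_equal(
                ra.feature_importances, rb.feature_importances
            )

    def test_l1o_tests_on_entire_held_out_cohort(self, rng):
        study = two_cohort_study(rng)
        config = ClassifierConfig("L1O", "B", "taxonomy", "CD",
                                  rf=FAST_RF, n_iterations=1)
        from phenomark.ml import _plan_iteration

        train_ids, test_ids = _plan_iteration(config, study, 0, 0)
        assert set(test_ids) == {"B"}
        assert len(test_ids["B"]) == 60  # every held-out sample
        assert "B" not in train_ids

    def test_missing_class_is_an_error(self, rng):
        study = two_cohort_study(rng)
        # a cohort with HC only
        idx = [f"C{i}" for i in range(20)]
        study.labels["C"] = pd.Series(["HC"] * 20, index=idx)
        study.features["taxonomy"]["C"] = pd.DataFrame(
            rng.random((20, 6)) / 10.0, index=idx,
            columns=[f"f{i}" for i in range(6)],
        )
        config = ClassifierConfig("Single", "C", "taxonomy", "CD",
                                  rf=FAST_RF, n_iterations=1)
        with pytest.raises(ValueError):
            train_and_evaluate(config, study, 0)

    def test_balanced_class_weights_formula(self):
        """Class weights are n / (k * n_c): counts 10 vs 30 give 2 and 2/3."""
        from sklearn.utils.class_weight import compute_class_weight

        y = np.array([0] * 10 + [1] * 30)
        w = compute_class_weight("balanced", classes=np.array([0, 1]), y=y)
        assert w[0] == pytest.approx(40 / (2 * 10))
        assert w[1] == pytest.approx(40 / (2 * 30))


class TestImportanceAggregation:
    def fake_results(self):
        from phenomark.ml import IterationResult

        r1 = IterationResult(1, 1, 1, pd.Series({"a": 0.6, "b": 0.4}), ["a", "b"])
        r2 = IterationResult(1, 1, 1, pd.Series({"a": 0.8, "c": 0.2}), ["a", "c"])
        return [r1, r2]

    def test_mean_importances_fill_zero(self):
        out = mean_importances(self.fake_results(), ["a", "b", "c"])
        assert out["a"] == pytest.approx(0.7)
        assert out["b"] == pytest.approx(0.2)

    def test_variant_importance_zeroed_when_missed_once(self):
        """A feature missed in any iteration carries zero for the variant."""
        out = variant_importances(self.fake_results())
        assert out["a"] == pytest.approx(0.7)
        assert out["b"] == 0.0 and out["c"] == 0.0
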