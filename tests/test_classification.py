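import json

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

import phenofreeze as pf
from phenofreeze.classification import ConfusionCounts, check_retrain_metadata
from phenofreeze.errors import (
    BundleFormatError,
    ConfigurationError,
    UndefinedValueError,
    ValidationError,
)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = pf.compute_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert (m.accuracy, m.sensitivity, m.specificity, m.f1) == (1, 1, 1, 1)

    def test_hand_computed_example(self):
        m = pf.compute_metrics(ConfusionCounts(tp=8, fp=1, tn=9, fn=2))
        assert m.accuracy == pytest.approx(0.85)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.9)
        assert m.f1 == pytest.approx(8 / 9.5)

    def test_empty_positive_class_flags_sensitivity(self):
        m = pf.compute_metrics(ConfusionCounts(tp=0, fp=1, tn=9, fn=0))
        assert "sensitivity" in m.undefined
        assert np.isnan(m.sensitivity)
        assert m.specificity == pytest.approx(0.9)

    def test_matches_brute_force_recount(self):
        """Formula evaluation equals recounting raw (prediction, truth) pairs."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = rng.integers(1, 50)
            pred = rng.choice([pf.SUSTAINED, pf.PHASIC], n)
            truth = rng.choice([pf.SUSTAINED, pf.PHASIC], n)
            c = ConfusionCounts.from_labels(pred, truth)
            # independent recount
            tp = sum(p == pf.SUSTAINED and t == pf.SUSTAINED
                     for p, t in zip(pred, truth))
            fp = sum(p == pf.SUSTAINED and t == pf.PHASIC
                     for p, t in zip(pred, truth))
            tn = sum(p == pf.PHASIC and t == pf.PHASIC
                     for p, t in zip(pred, truth))
            fn = sum(p == pf.PHASIC and t == pf.SUSTAINED
                     for p, t in zip(pred, truth))
            assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
            m = pf.compute_metrics(c)
            assert m.accuracy == pytest.approx((tp + tn) / n)
            if tp + fn:
                assert m.sensitivity == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert m.specificity == pytest.approx(tn / (tn + fp))
            if tp + fp + fn:
                assert m.f1 == pytest.approx(tp / (tp + 0.5 * (fp + fn)))


class TestAuroc:
    def test_perfect_separation(self):
        truth = [pf.SUSTAINED] * 3 + [pf.PHASIC] * 3
        assert pf.auroc([0.9, 0.8, 0.7, 0.3, 0.2, 0.1], truth) == 1.0

    def test_all_ties_half(self):
        truth = [pf.SUSTAINED] * 3 + [pf.PHASIC] * 3
        assert pf.auroc([0.5] * 6, truth) == 0.5

    def test_matches_pair_count_oracle(self):
        """AUROC equals the Mann-Whitney pair statistic counted directly."""
        rng = np.random.default_rng(23)
        for _ in range(30):
            n = int(rng.integers(6, 20))
            truth = np.array([pf.SUSTAINED] * (n // 2) + [pf.PHASIC] * (n - n // 2))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            pos = scores[truth == pf.SUSTAINED]
            neg = scores[truth == pf.PHASIC]
            wins = sum(
                1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg
            )
            oracle = wins / (len(pos) * len(neg))
            assert pf.auroc(scores, truth) == pytest.approx(oracle)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedValueError):
            pf.auroc([0.1, 0.2], [pf.SUSTAINED, pf.SUSTAINED])


class TestCohensKappa:
    def test_identical_labelings(self):
        a = [pf.SUSTAINED, pf.PHASIC, pf.SUSTAINED]
        assert pf.cohens_kappa(a, a) == 1.0

    def test_complementary_balanced(self):
        a = [pf.SUSTAINED] * 5 + [pf.PHASIC] * 5
        b = [pf.PHASIC] * 5 + [pf.SUSTAINED] * 5
        assert pf.cohens_kappa(a, b) == pytest.approx(-1.0)

    def test_near_perfect_concordance_example(self):
        """2x2 table (16,2 / 0,20) on n=38: two animals swap groups."""
        a = ([pf.SUSTAINED] * 18) + ([pf.PHASIC] * 20)
        b = ([pf.SUSTAINED] * 16 + [pf.PHASIC] * 2) + ([pf.PHASIC] * 20)
        k = pf.cohens_kappa(a, b)
        # hand computation: p_o = 36/38, p_e with marginals (18,20)x(16,22)
        p_o = 36 / 38
        p_e = (18 / 38) * (16 / 38) + (20 / 38) * (22 / 38)
        assert k == pytest.approx((p_o - p_e) / (1 - p_e))
        assert k == pytest.approx(0.894, abs=5e-3)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(2, 40))
            a = rng.choice([pf.SUSTAINED, pf.PHASIC], n)
            b = rng.choice([pf.SUSTAINED, pf.PHASIC], n)
            expected = cohen_kappa_score(a, b)
            if np.isnan(expected):  # both constant: our documented edge
                continue
            assert pf.cohens_kappa(a, b) == pytest.approx(expected)

    def test_constant_identical_labelings_defined_as_one(self):
        a = [pf.SUSTAINED] * 4
        assert pf.cohens_kappa(a, a) == 1.0


class TestTrainPredict:
    def test_separable_training_accuracy_one(self, separable_features):
        feats, truth = separable_features
        y = truth.loc[feats["animal_id"]].to_numpy()
        bundle = pf.train(feats, y, "logistic", seed=0)
        pred = pf.predict(bundle, feats)
        assert (pred["label"].to_numpy() == y).mean() == 1.0

    def test_single_class_rejected(self, separable_features):
        feats, _ = separable_features
        with pytest.raises(ValidationError):
            pf.train(feats, [pf.SUSTAINED] * len(feats), "logistic", seed=0)

    def test_unknown_algorithm_rejected(self, separable_features):
        feats, truth = separable_features
        with pytest.raises(ConfigurationError):
            pf.train(feats, truth.to_numpy(), "neural_net", seed=0)

    def test_deterministic_given_seed(self, separable_features, tmp_path):
        feats, truth = separable_features
        y = truth.loc[feats["animal_id"]].to_numpy()
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        pf.save_bundle(pf.train(feats, y, "random_forest", seed=9), p1)
        pf.save_bundle(pf.train(feats, y, "random_forest", seed=9), p2)
        assert p1.read_bytes() == p2.read_bytes()

    @pytest.mark.parametrize("algorithm", pf.ALGORITHMS)
    def test_centroid_animal_classified_sustained(
        self, separable_features, algorithm
    ):
        feats, truth = separable_features
        y = truth.loc[feats["animal_id"]].to_numpy()
        bundle = pf.train(feats, y, algorithm, seed=1)
        centroid = feats.loc[
            truth.loc[feats["animal_id"]].to_numpy() == pf.SUSTAINED,
            ["intercept", "slope", "sustained_mean"],
        ].mean()
        one = pd.DataFrame({"animal_id": ["c"], **{k: [v] for k, v in centroid.items()}})
        assert pf.predict(bundle, one).loc[0, "label"] == pf.SUSTAINED

    @pytest.mark.parametrize("algorithm", pf.ALGORITHMS)
    def test_batch_invariance_all_algorithms(self, small_fixture_bundle, algorithm):
        """predict({i}) equals predict(batch) restricted to i, exactly."""
        sub, y, _ = small_fixture_bundle
        bundle = pf.train(sub, y, algorithm, seed=2)
        batch = pf.predict(bundle, sub)
        for i in range(len(sub)):
            alone = pf.predict(bundle, sub.iloc[[i]].reset_index(drop=True))
            assert alone.loc[0, "label"] == batch.loc[i, "label"]
            assert alone.loc[0, "score"] == pytest.approx(
                batch.loc[i, "score"], abs=1e-12
            )

    def test_empty_feature_table(self, small_fixture_bundle):
        _, _, bundle = small_fixture_bundle
        out = pf.predict(bundle, pd.DataFrame(columns=["animal_id", "intercept",
                                                       "slope", "sustained_mean"]))
        assert len(out) == 0


class TestMonteCarloCV:
    def test_separable_mean_accuracy_one(self, separable_features):
        feats, truth = separable_features
        y = truth.loc[feats["animal_id"]].to_numpy()
        summary = pf.monte_carlo_cv(feats, y, "logistic", iters=50, seed=4)
        assert summary.mean["accuracy"] == 1.0

    def test_zero_iterations_rejected(self, separable_features):
        feats, truth = separable_features
        with pytest.raises(ConfigurationError):
            pf.monte_carlo_cv(feats, truth.to_numpy(), "logistic", iters=0)

    def test_label_permutation_null(self, separable_features):
        """Permuted labels: accuracy near the majority-class proportion."""
        feats, truth = separable_features
        rng = np.random.default_rng(12)
        y = rng.permutation(truth.loc[feats["animal_id"]].to_numpy())
        majority = max((y == pf.SUSTAINED).mean(), (y == pf.PHASIC).mean())
        summary = pf.monte_carlo_cv(feats, y, "logistic", iters=200, seed=4)
        assert abs(summary.mean["accuracy"] - majority) < 0.1

    def test_deterministic_given_seed(self, separable_features):
        feats, truth = separable_features
        y = truth.loc[feats["animal_id"]].to_numpy()
        s1 = pf.monte_carlo_cv(feats, y, "lda", iters=10, seed=8)
        s2 = pf.monte_carlo_cv(feats, y, "lda", iters=10, seed=8)
        pd.testing.assert_frame_equal(s1.per_iteration, s2.per_iteration)

    def test_stratified_split_keeps_both_classes(self, separable_features):
        feats, truth = separable_features
        sub = pd.concat([feats.iloc[:5], feats.iloc[100:103]], ignore_index=True)
        y = truth.loc[sub["animal_id"]].to_numpy()
        summary = pf.monte_carlo_cv(sub, y, "lda", iters=25, seed=1)
        assert summary.excluded_iterations == 0
        assert not summary.per_iteration["sensitivity"].isna().any()


class TestSelectBest:
    def make(self, algorithm, acc, sens=0.5, spec=0.5):
        return pf.MetricSummary(
            algorithm=algorithm, iterations=1, train_fraction=0.7,
            per_iteration=pd.DataFrame(),
            mean={"accuracy": acc, "sensitivity": sens, "specificity": spec},
            sd={},
        )

    def test_single_summary(self):
        assert pf.select_best([self.make("lda", 0.9)]) == "lda"

    def test_higher_accuracy_wins(self):
        s = [self.make("lda", 0.93), self.make("logistic", 0.95)]
        assert pf.select_best(s) == "logistic"

    def test_tie_broken_by_sensitivity(self):
        s = [self.make("lda", 0.95, sens=0.96), self.make("logistic", 0.95, sens=0.90)]
        assert pf.select_best(s) == "lda"

    def test_full_tie_uses_fixed_algorithm_order(self):
        s = [self.make("svm_rbf", 0.95), self.make("logistic", 0.95)]
        assert pf.select_best(s) == "logistic"

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            pf.select_best([])

    def test_registry_mirrors_best_models_per_setting(self):
        assert pf.MODEL_REGISTRY == {
            ("female", "MR1"): "logistic",
            ("female", "MR2"): "logistic",
            ("male", "MR1"): "random_forest",
            ("male", "MR2"): "svm_linear",
        }


class TestBundlePersistence:
    def test_round_trip_identical_predictions(self, small_fixture_bundle, tmp_path):
        sub, y, bundle = small_fixture_bundle
        path = tmp_path / "bundle.json"
        pf.save_bundle(bundle, path)
        reloaded = pf.load_bundle(path)
        p1 = pf.predict(bundle, sub)
        p2 = pf.predict(reloaded, sub)
        pd.testing.assert_frame_equal(p1, p2)

    def test_metadata_surfaced_on_load(self, small_fixture_bundle, tmp_path):
        _, _, bundle = small_fixture_bundle
        path = tmp_path / "bundle.json"
        pf.save_bundle(bundle, path)
        meta = pf.load_bundle(path).metadata
        assert meta["sex"] == "female"
        assert meta["session"] == "MR1"
        assert meta["training_n"] == 60

    def test_truncated_file_is_format_error(self, small_fixture_bundle, tmp_path):
        _, _, bundle = small_fixture_bundle
        path = tmp_path / "bundle.json"
        pf.save_bundle(bundle, path)
        path.write_text(path.read_text()[: 100])
        with pytest.raises(BundleFormatError):
            pf.load_bundle(path)

    def test_version_mismatch_rejected(self, small_fixture_bundle, tmp_path):
        _, _, bundle = small_fixture_bundle
        path = tmp_path / "bundle.json"
        pf.save_bundle(bundle, path)
        payload = json.loads(path.read_text())
        payload["format_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(BundleFormatError, match="version"):
            pf.load_bundle(path)


class TestRetrain:
    def test_empty_addition_equivalent_predictions(self, small_fixture_bundle):
        sub, y, bundle = small_fixture_bundle
        empty = sub.iloc[0:0]
        new = pf.retrain_with(bundle, empty, np.array([], dtype=object))
        pd.testing.assert_frame_equal(
            pf.predict(bundle, sub), pf.predict(new, sub)
        )

    def test_duplicate_training_set_same_boundary(self, small_fixture_bundle):
        """Doubling every training point leaves the logistic separator put."""
        sub, y, bundle = small_fixture_bundle
        dup = sub.copy()
        dup["animal_id"] = dup["animal_id"] + "_dup"
        new = pf.retrain_with(bundle, dup, y)
        pd.testing.assert_frame_equal(
            pf.predict(bundle, sub)[["animal_id", "label"]],
            pf.predict(new, sub)[["animal_id", "label"]],
        )

    def test_provenance_recorded(self, small_fixture_bundle):
        sub, y, bundle = small_fixture_bundle
        new = pf.retrain_with(bundle, sub.iloc[:4], y[:4])
        assert new.metadata["retrained_from_n"] == 60
        assert new.metadata["added_n"] == 4

    def test_mismatched_sex_rejected(self, small_fixture_bundle):
        sub, y, bundle = small_fixture_bundle
        with pytest.raises(ConfigurationError):
            pf.retrain_with(bundle, sub, y, sex="male")
        with pytest.raises(ConfigurationError):
            check_retrain_metadata(bundle, "male", "MR1")
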