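"""Top-N capture, AUC oracles, chi-square characterization, ELISpot rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from peptigen.eval_stats import (
    ElispotResult,
    ElispotThresholds,
    UndefinedMetricError,
    characterize_dataset,
    classify_elispot,
    feature_stats,
    roc_auc,
    top_n_capture,
)
from peptigen.records_io import Dataset
from peptigen.synthetic import GeneratorSpec, generate_training_set

from conftest import make_record


class TestTopN:
    def test_all_positives_first(self):
        order = [f"p{i}" for i in range(5)] + [f"n{i}" for i in range(20)]
        truth = {**{f"p{i}": "immunogenic" for i in range(5)},
                 **{f"n{i}": "non_immunogenic" for i in range(20)}}
        report = top_n_capture(order, truth, [10, 20])
        assert report.captured[10] == 5
        assert report.captured[20] == 5

    def test_random_ranking_matches_prefix_scan(self, rng):
        ids = [f"r{i}" for i in range(60)]
        labels = rng.choice(["immunogenic", "non_immunogenic"], size=60)
        truth = dict(zip(ids, labels))
        order = list(rng.permutation(ids))
        report = top_n_capture(order, truth, [10, 20, 50])
        for n in (10, 20, 50):
            brute = sum(truth[r] == "immunogenic" for r in order[:n])
            assert report.captured[n] == brute

    def test_monotone_in_n(self, rng):
        for _ in range(100):
            ids = [f"r{i}" for i in range(55)]
            truth = dict(zip(ids, rng.choice(["immunogenic", "non_immunogenic"], 55)))
            order = list(rng.permutation(ids))
            c = top_n_capture(order, truth, [10, 20, 50]).captured
            assert c[10] <= c[20] <= c[50]

    def test_missing_truth_id_raises(self):
        with pytest.raises(KeyError):
            top_n_capture(["a"], {}, [1])


def brute_force_auc(scores, labels):
    """O(n^2) pairwise oracle with half-credit ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=10_000)
        labels = rng.integers(0, 2, 10_000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_matches_pairwise_oracle_on_small_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 20))
            scores = np.round(rng.uniform(size=n), 1)  # force some ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.uniform(size=200)
        labels = rng.integers(0, 2, 200)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(size=100)
        labels = rng.integers(0, 2, 100)
        assert roc_auc(np.exp(3 * scores) - 5, labels) == pytest.approx(
            roc_auc(scores, labels), abs=1e-12
        )

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.9], [1, 1])


class TestCharacterization:
    def test_identical_length_distributions_give_p_near_one(self):
        recs = []
        for i in range(40):
            L = 8 + i % 4
            recs.append(make_record(f"p{i}", "A" * L, label="immunogenic"))
            recs.append(make_record(f"n{i}", "C" * L, label="non_immunogenic"))
        report = characterize_dataset(Dataset(records=recs))
        assert report.length_chi2 == pytest.approx(0.0, abs=1e-9)
        assert report.length_chi2_p == pytest.approx(1.0)

    def test_2x2_table_matches_hand_computed_chi_square(self):
        # 30 A vs 10 C in positives, 10 A vs 30 C in negatives at P1
        recs = (
            [make_record(f"a{i}", "ADDDDDDDD", label="immunogenic") for i in range(30)]
            + [make_record(f"b{i}", "CDDDDDDDD", label="immunogenic") for i in range(10)]
            + [make_record(f"c{i}", "ADDDDDDDD", label="non_immunogenic") for i in range(10)]
            + [make_record(f"d{i}", "CDDDDDDDD", label="non_immunogenic") for i in range(30)]
        )
        report = characterize_dataset(Dataset(records=recs))
        table = np.array([[30, 10], [10, 30]])
        expected_stat, expected_p, _, _ = stats.chi2_contingency(table)
        assert report.positional_chi2[1] == pytest.approx(expected_stat)
        assert report.positional_chi2_p[1] == pytest.approx(expected_p)

    def test_planted_enrichment_detected_across_seeds(self):
        """E/D enrichment at P2-P4 planted by the generator reaches
        significance at those positions, 3 seeds."""
        for seed in (0, 1, 2):
            ds, _ = generate_training_set(GeneratorSpec(n_records=1500, seed=seed))
            report = characterize_dataset(ds)
            for pos in (2, 3, 4):
                assert report.positional_chi2_p[pos] < 0.05, (seed, pos)

    def test_frequencies_sum_to_one_per_position(self, toy_dataset):
        report = characterize_dataset(toy_dataset)
        for lab, freq in report.residue_frequencies.items():
            sums = freq.sum(axis=0)
            nonzero = sums[sums > 0]
            assert np.allclose(nonzero, 1.0)

    def test_single_class_raises(self):
        ds = Dataset(records=[make_record("a", "SIINFEKLA")])
        with pytest.raises(UndefinedMetricError):
            characterize_dataset(ds)


class TestFeatureStats:
    def make_features(self, rng, n=60):
        X = pd.DataFrame(
            rng.normal(size=(n, 4)), columns=["F1", "F2", "F3", "F4"]
        )
        labels = rng.integers(0, 2, n)
        return X, labels

    def test_duplicated_feature_has_rho_one(self, rng):
        X, labels = self.make_features(rng)
        X["F5"] = X["F1"]
        report = feature_stats(X, labels, seed=0, n_trees=50)
        assert report.spearman.loc["F1", "F5"] == pytest.approx(1.0)

    def test_monotone_transform_has_rho_one(self, rng):
        X, labels = self.make_features(rng)
        X["F5"] = np.exp(X["F1"])
        report = feature_stats(X, labels, seed=0, n_trees=50)
        assert report.spearman.loc["F1", "F5"] == pytest.approx(1.0)

    def test_constant_feature_reported_as_undefined(self, rng):
        X, labels = self.make_features(rng)
        X["F5"] = 1.0
        report = feature_stats(X, labels, seed=0, n_trees=50)
        assert np.isnan(report.spearman.loc["F1", "F5"])
        assert ("F1", "F5") in report.undefined_pairs

    def test_planted_separating_feature_tops_importance(self):
        """One perfectly separating feature among noise wins RF importance
        across 3 seeds."""
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            labels = rng.integers(0, 2, 120)
            X = pd.DataFrame(rng.normal(size=(120, 5)), columns=[f"F{i}" for i in range(1, 6)])
            X["F3"] = labels * 4.0 + rng.normal(scale=0.1, size=120)
            report = feature_stats(X, labels, seed=seed, n_trees=200)
            assert report.rf_importance.index[0] == "F3"
            assert report.rf_importance.sum() == pytest.approx(1.0)

    def test_spearman_symmetric_unit_diagonal(self, rng):
        X, labels = self.make_features(rng)
        report = feature_stats(X, labels, seed=0, n_trees=20)
        m = report.spearman.values
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T, equal_nan=True)


class TestElispot:
    def res(self, counts, background=0.0, pid="p"):
        return ElispotResult(peptide_id=pid, replicate_counts=list(counts), background_mean=background)

    def test_threshold_boundaries(self):
        results, _ = classify_elispot(
            [self.res([81.0], pid="a"), self.res([8.0], pid="b"), self.res([7.9], pid="c")]
        )
        assert [r.response for r in results] == ["strong", "weak", "negative"]

    def test_background_subtraction_and_floor(self):
        results, _ = classify_elispot([self.res([5.0, 5.0, 5.0], background=20.0)])
        assert results[0].adjusted_count == 0.0
        assert results[0].response == "negative"

    def test_worked_example_rates_24_weak_5_strong_of_50(self):
        batch = (
            [self.res([120.0], pid=f"s{i}") for i in range(5)]
            + [self.res([40.0], pid=f"w{i}") for i in range(24)]
            + [self.res([2.0], pid=f"n{i}") for i in range(21)]
        )
        _, summary = classify_elispot(batch)
        assert summary.n_positive == 29
        assert summary.positive_rate == pytest.approx(58.0)
        assert summary.weak_rate == pytest.approx(48.0)
        assert summary.strong_rate == pytest.approx(10.0)

    def test_outlier_replicate_dropped(self):
        # one wild replicate >2 SD from the mean is removed before averaging
        results, _ = classify_elispot([self.res([10.0, 12.0, 11.0, 500.0])])
        assert results[0].dropped_replicates == 1
        assert results[0].adjusted_count == pytest.approx(11.0)

    def test_fewer_than_three_replicates_kept(self):
        results, _ = classify_elispot([self.res([10.0, 500.0])])
        assert results[0].dropped_replicates == 0

    def test_negative_count_raises(self):
        with pytest.raises(ValueError):
            classify_elispot([self.res([-1.0])])

    def test_classes_partition(self, rng):
        batch = [self.res(rng.uniform(0, 200, 3), background=5.0, pid=f"p{i}") for i in range(30)]
        results, summary = classify_elispot(batch)
        assert sum(r.response in ("weak", "strong", "negative") for r in results) == 30
        n_neg = sum(r.response == "negative" for r in results)
        assert n_neg + summary.n_positive == 30

    def test_thresholds_validate(self):
        with pytest.raises(ValueError):
            ElispotThresholds(weak_min=90, strong_min=81)

    def test_dataframe_input(self):
        df = pd.DataFrame(
            {"peptide_id": ["a"], "replicate1": [100.0], "replicate2": [102.0],
             "background_mean": [10.0]}
        )
        results, _ = classify_elispot(df)
        assert results[0].response == "strong"
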