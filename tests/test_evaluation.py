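import numpy as np
import pytest

import _oracles as orc
from eqtlcausal import UndefinedMetricError, infer_all
from eqtlcausal.evaluation import (
    RANK_BIN_PERCENTS,
    RankedPredictions,
    aupr,
    auroc,
    local_precision_by_confounding,
    precision_vs_estimated,
    scoreset_predictions,
    subsample_evaluate,
)
from eqtlcausal.scores import InferenceConfig


class TestAuroc:
    def test_perfect(self):
        assert auroc([3, 2, 1, 0], [1, 1, 0, 0]) == 1.0

    def test_reversed(self):
        assert auroc([0, 1, 2, 3], [1, 1, 0, 0]) == 0.0

    def test_matches_brute_force(self, rng):
        scores = rng.integers(0, 10, 20).astype(float)  # ties on purpose
        labels = rng.random(20) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert auroc(scores, labels) == pytest.approx(
            orc.brute_force_auroc(scores, labels), abs=1e-12)

    def test_one_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc([1.0, 2.0], [1, 1])

    def test_monotone_transform_invariant(self, rng):
        scores = rng.random(50)
        labels = rng.random(50) < 0.3
        labels[0] = True
        labels[1] = False
        assert auroc(np.exp(5 * scores), labels) == pytest.approx(
            auroc(scores, labels), abs=1e-12)


class TestAupr:
    def test_perfect(self):
        assert aupr([4, 3, 2, 1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        labels = [1, 0, 0, 0, 1, 0, 0, 0, 0, 0]
        assert aupr(np.ones(10), labels) == pytest.approx(0.2)

    def test_matches_exhaustive_interpolation(self, rng):
        for _ in range(5):
            scores = rng.integers(0, 6, 10).astype(float)
            labels = rng.random(10) < 0.4
            if not labels.any():
                labels[3] = True
            assert aupr(scores, labels) == pytest.approx(
                orc.exhaustive_aupr(scores, labels), abs=2e-4)

    def test_zero_positives_undefined(self):
        with pytest.raises(UndefinedMetricError):
            aupr([1.0, 2.0], [0, 0])

    def test_tie_permutation_invariant(self, rng):
        scores = np.array([3.0, 2.0, 2.0, 2.0, 1.0])
        labels = np.array([1, 1, 0, 0, 0])
        base = aupr(scores, labels)
        # permuting the tied block must not change the metric
        assert aupr(scores, np.array([1, 0, 0, 1, 0])) == pytest.approx(base)

    def test_better_than_random_beats_prevalence(self, rng):
        scores = rng.random(200)
        labels = (scores + rng.normal(0, 0.4, 200)) > 0.7
        if labels.any():
            assert aupr(scores, labels) >= labels.mean()


class TestSubsample:
    def test_full_size_zero_sd(self, tiny_dataset):
        expr, geno, pairs = tiny_dataset
        edges = {("G00", "G01")}
        df = subsample_evaluate(expr, geno, pairs, edges, N=expr.n_samples, k=3,
                               score_names=("Pnew",),
                               config=InferenceConfig(min_targets=5))
        assert np.allclose(df["sd"], 0.0)

    def test_oversized_subsample_rejected(self, tiny_dataset):
        expr, geno, pairs = tiny_dataset
        with pytest.raises(Exception):
            subsample_evaluate(expr, geno, pairs, {("G00", "G01")},
                               N=expr.n_samples + 1)

    def test_reports_mean_sd_se(self, tiny_dataset):
        expr, geno, pairs = tiny_dataset
        edges = {("G00", "G01")}
        df = subsample_evaluate(expr, geno, pairs, edges, N=30, k=4, seed=1,
                               score_names=("Pnew", "P0"),
                               config=InferenceConfig(min_targets=5))
        assert set(df["metric"]) == {"auroc", "aupr"}
        assert set(df["score"]) == {"Pnew", "P0"}
        np.testing.assert_allclose(df["se"], df["sd"] / 2.0)  # k = 4


class TestLocalPrecision:
    def _preds(self, n, frac_true, rng):
        scores = -np.arange(n, dtype=float)
        labels = rng.random(n) < frac_true
        conf = rng.random(n) < 0.5
        return RankedPredictions(scores, labels.astype(int), conf)

    def test_default_bins_match_published_ranges(self):
        assert RANK_BIN_PERCENTS == (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5,
                                     1.0, 10.0, 100.0)

    def test_all_true_gives_unit_precision(self, rng):
        preds = RankedPredictions(np.arange(1000.0), np.ones(1000, int),
                                  rng.random(1000) < 0.5)
        df = local_precision_by_confounding(preds)
        filled = df.dropna(subset=["precision"])
        assert (filled["precision"] == 1.0).all()

    def test_counts_partition_universe(self, rng):
        preds = self._preds(50000, 0.01, rng)
        df = local_precision_by_confounding(preds)
        assert df["total_count"].sum() == 50000

    def test_empty_subgroup_reported_as_nan(self):
        preds = RankedPredictions(np.arange(200.0), np.zeros(200, int),
                                  np.zeros(200, bool))
        df = local_precision_by_confounding(preds)
        confounded = df[df["subgroup"] == "confounded"]
        assert (confounded["total_count"] == 0).all()
        assert confounded["precision"].isna().all()

    def test_requires_confounded_flags(self):
        preds = RankedPredictions(np.arange(10.0), np.zeros(10, int))
        with pytest.raises(Exception):
            local_precision_by_confounding(preds)


class TestPrecisionVsEstimated:
    def test_above_one_cutoff_empty(self, rng):
        df = precision_vs_estimated(rng.random(100), rng.random(100) < 0.5,
                                    thresholds=(1.0 + 1e-9,))
        assert df["count"].iloc[0] == 0
        assert np.isnan(df["precision"].iloc[0])

    def test_default_cutoffs(self, rng):
        df = precision_vs_estimated(rng.random(50), rng.random(50) < 0.5)
        np.testing.assert_allclose(df["cutoff"], np.arange(0.1, 1.0, 0.1))

    def test_calibrated_scores_track_cutoffs(self, rng):
        scores = rng.random(20000)
        labels = rng.random(20000) < scores  # perfectly calibrated by design
        df = precision_vs_estimated(scores, labels)
        for _, row in df.iterrows():
            assert row["precision"] >= row["cutoff"] - 0.1


class TestScoresetPredictions:
    def test_labels_and_flags(self, tiny_dataset):
        expr, geno, pairs = tiny_dataset
        ss = infer_all(expr, geno, pairs, InferenceConfig(min_targets=5))
        edges = {("G00", "G01")}
        conf = {("G02", "G03")}
        preds = scoreset_predictions(ss, "Pnew", edges, conf)
        n_pairs = len(ss.pair_gene_ids) * (len(ss.target_gene_ids) - 1)
        assert preds.scores.size == n_pairs
        assert preds.labels.sum() == 1
        assert preds.confounded.sum() == 1
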