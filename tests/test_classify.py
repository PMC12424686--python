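"""Frozen-base classification: shuffling, CV, metrics, mutation-bin grids."""

import numpy as np
import pytest

import ablmkit as ak
from ablmkit.classify import (
    FinetuneConfig,
    SingleClassError,
    StratificationError,
    build_shuffled_pair_dataset,
    compute_metrics,
    crossval_features,
    embed_pairs,
    mutation_bin_accuracy,
)


class TestShuffledPairs:
    def test_balanced_and_deranged(self, repertoire):
        ds = build_shuffled_pair_dataset(repertoire, np.random.default_rng(0))
        y = ds.labels()
        assert (y == 0).sum() == (y == 1).sum()
        native_light = {p.pair_id: p.light_aa for p in repertoire}
        for pair, label in ds.items:
            if label == 1:
                original = native_light[pair.pair_id.removesuffix("|shuf")]
                assert pair.light_aa != original

    def test_four_pair_donor(self, repertoire):
        donor = [p for p in repertoire if p.donor_id == "donor_000"][:4]
        ds = build_shuffled_pair_dataset(donor, np.random.default_rng(1))
        y = ds.labels()
        assert len(ds) == 4 and (y == 0).sum() == 2 and (y == 1).sum() == 2

    def test_marginal_chain_multisets_preserved(self, repertoire):
        donor = [p for p in repertoire if p.donor_id == "donor_001"]
        ds = build_shuffled_pair_dataset(donor, np.random.default_rng(2))
        # every used heavy appears once; the shuffled half's lights are a
        # permutation of the same half's native lights
        shuffled = [p for p, lab in ds.items if lab == 1]
        originals = {p.pair_id: p for p in donor}
        native_of_shuffled = [
            originals[p.pair_id.removesuffix("|shuf")] for p in shuffled
        ]
        assert sorted(p.light_aa for p in shuffled) == sorted(
            p.light_aa for p in native_of_shuffled
        )
        assert [p.heavy_aa for p in shuffled] == [p.heavy_aa for p in native_of_shuffled]


class TestEmbeddings:
    def test_deterministic_and_dimensioned(self, untrained_model, repertoire):
        reps1 = embed_pairs(untrained_model, repertoire[:6])
        reps2 = embed_pairs(untrained_model, repertoire[:6])
        np.testing.assert_array_equal(reps1, reps2)
        assert reps1.shape == (6, untrained_model.config.d_model)

    def test_identical_items_identical_representations(self, untrained_model, repertoire):
        reps = embed_pairs(untrained_model, [repertoire[0], repertoire[0]],
                           pooling="mean_over_residues")
        np.testing.assert_allclose(reps[0], reps[1])

    def test_batch_order_invariance(self, untrained_model, repertoire):
        fwd = embed_pairs(untrained_model, repertoire[:8])
        rev = embed_pairs(untrained_model, repertoire[:8][::-1])
        np.testing.assert_allclose(fwd, rev[::-1], atol=1e-10)


class TestCrossValidation:
    def _blobs(self, n=150, sep=8.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        y = (np.arange(n) % 2).astype(int)
        X[y == 1, 0] += sep
        return X, y

    def test_separable_blobs_classified(self):
        X, y = self._blobs()
        cfg = FinetuneConfig(epochs=100, batch_size=32, peak_lr=0.05, folds=5, seed=1)
        result = crossval_features(X, y, cfg)
        assert result.metrics_mean["accuracy"] >= 0.95

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(200, 6))
        y = rng.integers(0, 2, 200)
        cfg = FinetuneConfig(epochs=20, batch_size=32, peak_lr=0.05, folds=5, seed=2)
        result = crossval_features(X, y, cfg)
        band = max(3 * result.metrics_se["accuracy"], 0.10)
        assert abs(result.metrics_mean["accuracy"] - 0.5) <= band

    def test_every_item_predicted_exactly_once(self):
        X, y = self._blobs(n=103)
        cfg = FinetuneConfig(epochs=5, batch_size=32, peak_lr=0.05, folds=5, seed=3)
        result = crossval_features(X, y, cfg)
        all_idx = np.concatenate(result.fold_indices)
        assert sorted(all_idx) == list(range(103))
        sizes = [len(i) for i in result.fold_indices]
        assert max(sizes) - min(sizes) <= 1

    def test_small_class_rejected(self):
        X = np.zeros((10, 2))
        y = np.array([0] * 8 + [1] * 2)
        with pytest.raises(StratificationError):
            crossval_features(X, y, FinetuneConfig(folds=5))


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        scores = np.column_stack([1.0 - y, y.astype(float)])
        m = compute_metrics(y, y, scores)
        assert m["accuracy"] == m["f1"] == m["mcc"] == 1.0
        assert m["auc"] == m["aupr"] == 1.0

    def test_uninformative_predictions(self):
        labels = np.array([1, 0, 1, 0])
        preds = np.array([1, 1, 0, 0])
        m = compute_metrics(labels, preds, np.full((4, 2), 0.5))
        assert m["accuracy"] == 0.5
        assert m["mcc"] == 0.0
        assert m["auc"] == 0.5  # all-tied scores

    def test_matches_brute_force_confusion_counts(self):
        labels = np.array([0, 0, 0, 1, 1, 1, 1, 0, 1, 0, 1, 0])
        preds = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 1, 0, 0])
        scores = np.column_stack([1.0 - preds, preds.astype(float)])
        m = compute_metrics(labels, preds, scores)
        tp = int(((labels == 1) & (preds == 1)).sum())
        tn = int(((labels == 0) & (preds == 0)).sum())
        fp = int(((labels == 0) & (preds == 1)).sum())
        fn = int(((labels == 1) & (preds == 0)).sum())
        assert m["accuracy"] == pytest.approx((tp + tn) / 12)
        assert m["f1"] == pytest.approx(2 * tp / (2 * tp + fp + fn))
        mcc = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert m["mcc"] == pytest.approx(mcc)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            compute_metrics([1, 1, 1], [1, 1, 1], np.ones((3, 2)) * 0.5)

    def test_three_way_metrics_are_macro(self):
        labels = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0])
        preds = np.array([0, 1, 2, 0, 1, 0, 2, 1, 2, 0])
        scores = np.full((10, 3), 1 / 3)
        scores[np.arange(10), preds] = 0.5
        scores /= scores.sum(axis=1, keepdims=True)
        m = compute_metrics(labels, preds, scores)
        from sklearn.metrics import f1_score

        assert m["f1"] == pytest.approx(f1_score(labels, preds, average="macro"))


class TestMutationBins:
    def test_all_correct_gives_unit_cells_and_occupancy(self, repertoire):
        ds = build_shuffled_pair_dataset(repertoire, np.random.default_rng(3))
        y = ds.labels()
        result = ak.CVResult(
            fold_indices=[np.arange(len(ds))],
            fold_labels=[y],
            fold_predictions=[y.copy()],
            fold_scores=[np.eye(2)[y]],
            metrics_per_fold=[{}],
        )
        bins = [0, 1, 8, 1000]
        acc, counts = mutation_bin_accuracy(result, ds, bins)
        assert counts.sum() == len(ds)
        assert np.all(acc[counts > 0] == 1.0)

    def test_class_filter_views_partition(self, repertoire):
        ds = build_shuffled_pair_dataset(repertoire, np.random.default_rng(4))
        y = ds.labels()
        result = ak.CVResult(
            fold_indices=[np.arange(len(ds))],
            fold_labels=[y],
            fold_predictions=[y.copy()],
            fold_scores=[np.eye(2)[y]],
            metrics_per_fold=[{}],
        )
        bins = [0, 1, 8, 1000]
        _, all_counts = mutation_bin_accuracy(result, ds, bins)
        _, native = mutation_bin_accuracy(result, ds, bins, class_filter=0)
        _, shuffled = mutation_bin_accuracy(result, ds, bins, class_filter=1)
        np.testing.assert_array_equal(all_counts, native + shuffled)


def test_uncorrelated_loads_defeat_mutation_count_heuristic(library):
    """With pairing_correlation=0, a classifier using only the heavy/light
    mutation-count difference cannot beat chance on native-vs-shuffled."""
    cfg = ak.RepertoireConfig(n_donors=4, pairs_per_donor=250, seed=21,
                              pairing_correlation=0.0, unmutated_fraction=0.0)
    pairs = ak.generate_repertoire(cfg, library)
    ds = build_shuffled_pair_dataset(pairs, np.random.default_rng(5))
    X = np.array(
        [[abs(p.heavy_mut_count - p.light_mut_count)] for p, _ in ds.items], float
    )
    y = ds.labels()
    result = crossval_features(
        X, y, FinetuneConfig(epochs=30, batch_size=64, peak_lr=0.05, folds=5, seed=6)
    )
    assert abs(result.metrics_mean["accuracy"] - 0.5) < 0.06


def test_correlated_loads_enable_mutation_count_heuristic(library):
    """With strong pairing correlation the same |heavy - light| feature
    separates native from shuffled pairs well above chance."""
    cfg = ak.RepertoireConfig(n_donors=4, pairs_per_donor=250, seed=22,
                              pairing_correlation=0.9, unmutated_fraction=0.0)
    pairs = ak.generate_repertoire(cfg, library)
    ds = build_shuffled_pair_dataset(pairs, np.random.default_rng(6))
    X = np.array(
        [[abs(p.heavy_mut_count - p.light_mut_count)] for p, _ in ds.items], float
    )
    y = ds.labels()
    result = crossval_features(
        X, y, FinetuneConfig(epochs=30, batch_size=64, peak_lr=0.05, folds=5, seed=7)
    )
    assert result.metrics_mean["accuracy"] > 0.6
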