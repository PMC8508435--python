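"""Metrics (MCC, AUC), rank machinery and dataset-characterisation stats."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef, roc_auc_score, silhouette_score

from melcaps.data import LabeledImageSet
from melcaps.evaluation import (
    ConfusionCounts,
    auc,
    average_ranks,
    borda_aggregate,
    class_distance_stats,
    imbalance_ratio,
    marginal_value_ranking,
    mcc,
    silhouette,
)
from melcaps.oracles import auc_pairs, mcc_loop

# Published optimizer-comparison MCC matrix (rows = 11 datasets,
# columns = ADAM, RMSProp, SGD) used as input for the rank machinery.
OPTIMIZER_MCC = np.array(
    [
        [0.065, 0.066, 0.242],
        [0.000, 0.000, 0.000],
        [0.000, 0.000, 0.000],
        [0.142, 0.182, 0.308],
        [0.015, 0.016, 0.026],
        [0.072, 0.024, 0.029],
        [0.000, 0.000, 0.000],
        [0.014, 0.014, 0.017],
        [0.116, 0.159, 0.458],
        [0.042, 0.089, 0.214],
        [0.132, 0.148, 0.123],
    ]
)

# Published average-rank row of the 4x4 capsule-dimension grid
# (primary caps dim, class caps features) -> Friedman average rank.
GRID_AVERAGE_RANKS = {
    (8, 16): 10.182, (8, 32): 10.455, (8, 48): 8.955, (8, 64): 7.909,
    (16, 16): 10.045, (16, 32): 7.909, (16, 48): 7.909, (16, 64): 4.091,
    (24, 16): 8.227, (24, 32): 7.955, (24, 48): 8.182, (24, 64): 8.727,
    (32, 16): 7.545, (32, 32): 7.727, (32, 48): 9.818, (32, 64): 10.364,
}


class TestMCC:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((50, 50, 0, 0), 1.0),  # perfect prediction
            ((25, 25, 25, 25), 0.0),  # random-equivalent
            ((40, 45, 5, 10), 0.7035),
        ],
    )
    def test_closed_form_values(self, counts, expected):
        tp, tn, fp, fn = counts
        assert mcc(ConfusionCounts(tp, tn, fp, fn)) == pytest.approx(expected, abs=1e-4)

    def test_degenerate_margin_returns_zero(self):
        assert mcc(ConfusionCounts(tp=0, tn=10, fp=0, fn=5)) == 0.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            mcc(ConfusionCounts(0, 0, 0, 0))

    def test_matches_loop_oracle_and_sklearn(self, rng):
        for _ in range(100):
            tp, tn, fp, fn = rng.integers(0, 40, size=4)
            if tp + tn + fp + fn == 0:
                continue
            ours = mcc(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert ours == pytest.approx(mcc_loop(tp, tn, fp, fn), abs=1e-12)
            y_true = [1] * (tp + fn) + [0] * (tn + fp)
            y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
            if len(set(y_true)) == 2:
                assert ours == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-9)
            assert -1.0 <= ours <= 1.0

    def test_label_swap_antisymmetry(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = (int(x) for x in rng.integers(1, 40, size=4))
            assert mcc(ConfusionCounts(fn, fp, tn, tp)) == pytest.approx(
                -mcc(ConfusionCounts(tp, tn, fp, fn)), abs=1e-12
            )


class TestAUC:
    def test_perfect_separation(self):
        assert auc(([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])) == 1.0

    def test_all_tied_scores(self):
        assert auc(([1, 1, 0, 0], [0.5, 0.5, 0.5, 0.5])) == 0.5

    def test_three_of_four_concordant(self):
        assert auc(([1, 1, 0, 0], [0.8, 0.4, 0.6, 0.2])) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(([1, 1], [0.2, 0.3]))

    def test_matches_pair_counting_and_trapezoid(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            s = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            ours = auc((y, s))
            assert ours == pytest.approx(auc_pairs(y, s), abs=1e-9)
            assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-9)  # trapezoid
            assert 0.0 <= ours <= 1.0

    def test_score_reversal_maps_to_complement(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        s = rng.random(50)
        assert auc((y, -s)) == pytest.approx(1.0 - auc((y, s)), abs=1e-12)


class TestAverageRanks:
    def test_reproduces_published_optimizer_ranking(self):
        ranks = average_ranks(OPTIMIZER_MCC)
        assert np.round(ranks, 3).tolist() == [2.409, 2.045, 1.545]

    def test_full_tie_gives_midrank(self):
        assert np.allclose(average_ranks(np.ones((5, 3))), 2.0)

    def test_dominant_method_ranks_first(self, rng):
        scores = rng.random((8, 4))
        scores[:, 2] = 2.0  # strictly best everywhere
        assert average_ranks(scores)[2] == 1.0

    def test_rank_rows_conserve_total(self, rng):
        from scipy.stats import rankdata

        scores = rng.choice([0.0, 0.1, 0.2], size=(6, 5))
        ranks = rankdata(-scores, axis=1)
        assert np.allclose(ranks.sum(axis=1), 5 * 6 / 2)

    def test_missing_scores_rejected(self):
        with pytest.raises(ValueError):
            average_ranks(np.array([[1.0, np.nan]]))


class TestBorda:
    def test_single_ranking_unchanged(self):
        assert borda_aggregate([["a", "b", "c"]]) == ["a", "b", "c"]

    def test_tie_broken_by_identifier(self):
        # scores: A = 3, B = 3, C = 0 -> tie on A/B resolved alphabetically
        assert borda_aggregate([["A", "B", "C"], ["B", "A", "C"]]) == ["A", "B", "C"]

    def test_inconsistent_element_sets_rejected(self):
        with pytest.raises(ValueError):
            borda_aggregate([["a", "b"], ["a", "c"]])

    def test_class_caps_consensus_from_published_grid(self):
        """Marginalising the published grid ranks over the class-caps value
        reproduces the reported consensus order 64 > 32 > 48 > 16."""
        order = marginal_value_ranking(GRID_AVERAGE_RANKS, value_of=lambda cfg: cfg[1])
        assert order == [64, 32, 48, 16]

    def test_primary_caps_best_and_worst(self):
        order = marginal_value_ranking(GRID_AVERAGE_RANKS, value_of=lambda cfg: cfg[0])
        assert order[0] == 16 and order[-1] == 8


class TestImbalanceRatio:
    def test_reported_style_ratio(self):
        labels = [0] * 100 + [1] * 70
        assert imbalance_ratio(labels) == pytest.approx(1.429, abs=5e-4)

    def test_equal_and_skewed(self):
        assert imbalance_ratio([0, 1] * 10) == 1.0
        assert imbalance_ratio([0] * 120 + [1] * 20) == 6.0

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            imbalance_ratio([0, 0, 0])


def _image_set(arrays, labels):
    return LabeledImageSet(images=[np.asarray(a, dtype=float) for a in arrays],
                           labels=np.asarray(labels))


class TestDistanceStats:
    def test_identical_everything_gives_ratio_one(self):
        img = np.full((4, 4, 3), 0.5)
        data = _image_set([img] * 4, [0, 0, 1, 1])
        st = class_distance_stats(data)
        assert st.intra_class == 0.0 and st.inter_class == 0.0
        assert st.dist_ratio == 1.0

    def test_constant_classes_closed_form(self):
        a = np.zeros((4, 4, 3))
        b = np.ones((4, 4, 3))
        data = _image_set([a, a, b, b], [0, 0, 1, 1])
        st = class_distance_stats(data)
        assert st.intra_class == 0.0
        assert st.inter_class == pytest.approx(np.sqrt(4 * 4 * 3) * 255.0)

    def test_matches_pairwise_loop_oracle(self, rng):
        imgs = [rng.random((3, 3, 3)) for _ in range(6)]
        labels = [0, 0, 0, 1, 1, 1]
        st = class_distance_stats(_image_set(imgs, labels))
        flat = [im.reshape(-1) * 255.0 for im in imgs]
        intra, inter = [], []
        for i in range(6):
            for j in range(i + 1, 6):
                d = float(np.sqrt(((flat[i] - flat[j]) ** 2).sum()))
                (intra if labels[i] == labels[j] else inter).append(d)
        assert st.intra_class == pytest.approx(np.mean(intra), abs=1e-9)
        assert st.inter_class == pytest.approx(np.mean(inter), abs=1e-9)
        assert st.dist_ratio == pytest.approx(np.mean(intra) / np.mean(inter), abs=1e-9)

    def test_tiny_class_rejected(self, rng):
        data = _image_set([rng.random((2, 2, 3)) for _ in range(3)], [0, 0, 1])
        with pytest.raises(ValueError):
            class_distance_stats(data)


class TestSilhouette:
    def test_tight_separated_clusters(self, rng):
        a = [np.zeros((2, 2, 3)) + rng.normal(0, 0.001, (2, 2, 3)) for _ in range(5)]
        b = [np.ones((2, 2, 3)) + rng.normal(0, 0.001, (2, 2, 3)) for _ in range(5)]
        val = silhouette(_image_set(a + b, [0] * 5 + [1] * 5))
        assert val > 0.9

    def test_interleaved_clusters_near_zero(self, rng):
        imgs = [rng.random((2, 2, 3)) for _ in range(20)]
        val = silhouette(_image_set(imgs, [0, 1] * 10))
        assert abs(val) < 0.25

    def test_hand_worked_four_point_configuration(self):
        # 1-D "images" at 0, 1 (class 0) and 4, 5 (class 1):
        # s = mean(3.5/4.5, 2.5/3.5, 2.5/3.5, 3.5/4.5) = 0.746031...
        imgs = [np.full((1, 1, 3), 0.0), np.full((1, 1, 3), 0.0),
                np.full((1, 1, 3), 0.0), np.full((1, 1, 3), 0.0)]
        for img, x in zip(imgs, [0.0, 1.0, 4.0, 5.0]):
            img[0, 0, 0] = x
        val = silhouette(_image_set(imgs, [0, 0, 1, 1]), pixel_scale=1.0)
        expected = (3.5 / 4.5 + 2.5 / 3.5 + 2.5 / 3.5 + 3.5 / 4.5) / 4
        assert val == pytest.approx(expected, abs=1e-9)

    def test_matches_sklearn(self, rng):
        imgs = [rng.random((3, 3, 3)) for _ in range(12)]
        labels = [0] * 6 + [1] * 6
        ours = silhouette(_image_set(imgs, labels))
        x = np.stack([im.reshape(-1) for im in imgs]) * 255.0
        assert ours == pytest.approx(silhouette_score(x, labels), abs=1e-9)
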