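import numpy as np
import pandas as pd
import pytest

from cortexscreen.classifier import (
    ConfusionMatrix,
    ForestConfig,
    build_pixel_dataset,
    dilate_mask,
    evaluate,
    importance_histogram,
    importance_table,
    split_train_test,
    train_forest,
)
from cortexscreen.projection import SurfaceProjection


def brute_force_dilate(mask, iterations):
    """Set-based 4-neighbor dilation, independent of scipy."""
    current = {tuple(p) for p in np.argwhere(mask)}
    h, w = mask.shape
    for _ in range(iterations):
        added = set()
        for j, k in current:
            for dj, dk in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nj, nk = j + dj, k + dk
                if 0 <= nj < h and 0 <= nk < w:
                    added.add((nj, nk))
        current |= added
    out = np.zeros_like(mask)
    for j, k in current:
        out[j, k] = True
    return out


def make_projection(values, gene_id="g", kind="top"):
    return SurfaceProjection(kind=kind, values=np.asarray(values, dtype=np.float64), gene_id=gene_id)


def gini(y):
    if len(y) == 0:
        return 0.0
    p = np.bincount(y, minlength=2) / len(y)
    return float(np.sum(p * (1.0 - p)))


def brute_force_importances(tree_clf, X, y):
    """Re-derive per-feature Gini reductions by re-partitioning the data."""
    t = tree_clf.tree_
    X32 = X.astype(np.float32)
    n_total = len(y)
    acc = np.zeros(X.shape[1])

    def walk(node, idx):
        f = t.feature[node]
        if f < 0:
            return
        left_sel = X32[idx, f] <= t.threshold[node]
        left, right = idx[left_sel], idx[~left_sel]
        n = len(idx)
        decrease = (n / n_total) * (
            gini(y[idx]) - len(left) / n * gini(y[left]) - len(right) / n * gini(y[right])
        )
        acc[f] += decrease
        walk(t.children_left[node], left)
        walk(t.children_right[node], right)

    walk(0, np.arange(n_total))
    return acc / acc.sum()


@pytest.fixture()
def small_dataset(rng):
    """200 pixels x 5 genes: gene 0 informative, rest noise."""
    n = 200
    y = (rng.random(n) < 0.5).astype(np.int64)
    X = rng.random((n, 5))
    X[:, 0] = np.where(y == 1, 0.8, 0.2) + rng.normal(0, 0.05, n)
    X = np.clip(X, 0, 1)
    from cortexscreen.classifier import PixelDataset

    return PixelDataset(
        area_id=1,
        pixel_rows=np.arange(n),
        pixel_cols=np.zeros(n, dtype=np.int64),
        X=X,
        y=y,
        gene_ids=[f"g{i}" for i in range(5)],
    )


class TestDilateMask:
    def test_zero_iterations_is_identity(self, rng):
        mask = rng.random((20, 20)) > 0.8
        mask[0, 0] = True
        np.testing.assert_array_equal(dilate_mask(mask, 0), mask)

    def test_center_pixel_two_iterations_is_13_pixel_diamond(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        out = dilate_mask(mask, 2)
        assert out.sum() == 13
        jj, kk = np.nonzero(out)
        assert (np.abs(jj - 4) + np.abs(kk - 4) <= 2).all()

    def test_matches_brute_force_oracle(self, rng):
        mask = np.zeros((40, 40), dtype=bool)
        mask[rng.integers(10, 30, 5), rng.integers(10, 30, 5)] = True
        for iterations in (1, 3, 7):
            np.testing.assert_array_equal(
                dilate_mask(mask, iterations), brute_force_dilate(mask, iterations)
            )

    def test_superset_and_monotone_growth(self, rng):
        mask = rng.random((25, 25)) > 0.9
        mask[12, 12] = True
        prev = dilate_mask(mask, 0)
        for it in (1, 2, 5, 10):
            cur = dilate_mask(mask, it)
            assert (cur | prev).sum() == cur.sum()  # prev subset of cur
            prev = cur

    def test_footprint_intersection_keeps_input(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        footprint = np.zeros((10, 10), dtype=bool)
        footprint[5, 6] = True
        out = dilate_mask(mask, 3, footprint=footprint)
        assert out[5, 5] and out[5, 6] and out.sum() == 2

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            dilate_mask(np.zeros((5, 5), dtype=bool), 2)


class TestBuildPixelDataset:
    def test_neighborhood_equal_to_mask_gives_all_ones(self, rng):
        vals = rng.random((8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:5, 2:5] = True
        ds = build_pixel_dataset([make_projection(vals)], mask, mask)
        assert (ds.y == 1).all()
        assert ds.n_pixels == mask.sum()

    def test_single_uniform_gene_gives_constant_column(self):
        vals = np.full((6, 6), 0.4)
        mask = np.ones((6, 6), dtype=bool)
        ds = build_pixel_dataset([make_projection(vals)], mask, mask)
        assert (ds.X[:, 0] == 0.4).all()

    def test_size_matches_hand_count(self, top_projections, top_area_masks):
        amask = top_area_masks[10]
        neighborhood = dilate_mask(amask.mask, 5)
        ds = build_pixel_dataset(top_projections, amask.mask, neighborhood)
        valid = np.ones(top_projections[0].values.shape, dtype=bool)
        for p in top_projections:
            valid &= np.isfinite(p.values)
        assert ds.n_pixels == int((neighborhood & valid).sum())
        assert ds.n_genes == len(top_projections)
        assert ds.gene_ids == [p.gene_id for p in top_projections]

    def test_kind_mismatch_raises(self, rng):
        vals = rng.random((4, 4))
        mask = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="kind"):
            build_pixel_dataset(
                [make_projection(vals, kind="top"), make_projection(vals, kind="flatmap")],
                mask,
                mask,
            )

    def test_labels_match_area_mask(self, rng):
        vals = rng.random((8, 8))
        area = np.zeros((8, 8), dtype=bool)
        area[1:4, 1:4] = True
        hood = dilate_mask(area, 2)
        ds = build_pixel_dataset([make_projection(vals)], area, hood)
        expected = area[ds.pixel_rows, ds.pixel_cols]
        np.testing.assert_array_equal(ds.y.astype(bool), expected)


class TestSplitTrainTest:
    def test_boundary_one_training_pixel(self, small_dataset):
        small_dataset_101 = small_dataset
        small_dataset_101.X = small_dataset.X[:101]
        small_dataset_101.y = small_dataset.y[:101]
        train, test = split_train_test(small_dataset_101, n_test=100, seed=0)
        assert len(train) == 1 and len(test) == 100
        assert len(np.intersect1d(train, test)) == 0

    def test_deterministic_and_exhaustive(self, small_dataset):
        t1 = split_train_test(small_dataset, n_test=50, seed=7)
        t2 = split_train_test(small_dataset, n_test=50, seed=7)
        np.testing.assert_array_equal(t1[0], t2[0])
        np.testing.assert_array_equal(t1[1], t2[1])
        merged = np.sort(np.concatenate(t1))
        np.testing.assert_array_equal(merged, np.arange(small_dataset.n_pixels))

    def test_too_small_raises(self, small_dataset):
        with pytest.raises(ValueError, match="too small"):
            split_train_test(small_dataset, n_test=small_dataset.n_pixels, seed=0)

    def test_test_fraction_tracks_dataset_fraction(self, small_dataset):
        # Monte-Carlo over seeds: unstratified sampling preserves the inside
        # fraction on average (binomial tolerance on the mean of 1000 draws).
        inside_frac = small_dataset.y.mean()
        n_test = 40
        fractions = [
            small_dataset.y[split_train_test(small_dataset, n_test=n_test, seed=s)[1]].mean()
            for s in range(1000)
        ]
        mean = np.mean(fractions)
        se = np.sqrt(inside_frac * (1 - inside_frac) / n_test / 1000)
        assert abs(mean - inside_frac) < 5 * se


class TestTrainForestAndEvaluate:
    def test_separable_single_gene_perfect_training_accuracy(self, rng):
        n = 300
        y = (rng.random(n) < 0.5).astype(np.int64)
        X = np.where(y[:, None] == 1, 0.9, 0.1) + np.zeros((n, 1))
        from cortexscreen.classifier import PixelDataset

        ds = PixelDataset(1, np.arange(n), np.zeros(n, dtype=np.int64), X, y, ["g0"])
        train, test = split_train_test(ds, n_test=100, seed=0)
        forest = train_forest(ds, train, ForestConfig(n_trees=10))
        assert (forest.predict(ds.X[train]) == ds.y[train]).all()
        cm = evaluate(forest, ds, test)
        assert cm.accuracy == 1.0
        assert cm.fn == 0 and cm.fp == 0

    def test_constant_features_predict_majority_class(self, rng):
        n = 200
        y = np.concatenate([np.ones(140, dtype=np.int64), np.zeros(60, dtype=np.int64)])
        X = np.full((n, 3), 0.5)
        from cortexscreen.classifier import PixelDataset

        ds = PixelDataset(1, np.arange(n), np.zeros(n, dtype=np.int64), X, y, ["a", "b", "c"])
        train = np.arange(n)
        forest = train_forest(ds, train, ForestConfig(n_trees=10))
        assert (forest.predict(ds.X) == 1).all()

    def test_fixed_seed_identical_predictions(self, small_dataset):
        train, test = split_train_test(small_dataset, n_test=50, seed=1)
        f1 = train_forest(small_dataset, train, ForestConfig(n_trees=20, random_state=0))
        f2 = train_forest(small_dataset, train, ForestConfig(n_trees=20, random_state=0))
        np.testing.assert_array_equal(f1.predict(small_dataset.X), f2.predict(small_dataset.X))

    def test_single_class_training_raises(self, small_dataset):
        idx = np.nonzero(small_dataset.y == 1)[0]
        with pytest.raises(ValueError, match="single class"):
            train_forest(small_dataset, idx, ForestConfig())

    def test_empty_test_set_raises(self, small_dataset):
        train, _ = split_train_test(small_dataset, n_test=50, seed=0)
        forest = train_forest(small_dataset, train, ForestConfig(n_trees=5))
        with pytest.raises(ValueError, match="empty"):
            evaluate(forest, small_dataset, np.array([], dtype=np.int64))


class TestConfusionMatrix:
    def test_paper_worked_example(self):
        # 52/54 correct inside, 44/46 correct outside -> 96% combined
        cm = ConfusionMatrix(tp=52, fn=2, fp=2, tn=44)
        assert cm.n_test == 100
        assert cm.accuracy == 0.96

    def test_counts_conserved(self, small_dataset):
        train, test = split_train_test(small_dataset, n_test=60, seed=2)
        forest = train_forest(small_dataset, train, ForestConfig(n_trees=10))
        cm = evaluate(forest, small_dataset, test)
        assert cm.n_test == 60
        assert 0.0 <= cm.accuracy <= 1.0


class TestImportanceTable:
    def test_sums_to_one(self, small_dataset):
        train, _ = split_train_test(small_dataset, n_test=50, seed=0)
        forest = train_forest(small_dataset, train, ForestConfig(n_trees=50))
        table = importance_table(forest, small_dataset.gene_ids)
        assert table["importance"].sum() == pytest.approx(1.0, abs=1e-9)
        assert sorted(table["rank"]) == [1, 2, 3, 4, 5]

    def test_informative_gene_ranks_first(self, small_dataset):
        train, _ = split_train_test(small_dataset, n_test=50, seed=0)
        forest = train_forest(small_dataset, train, ForestConfig(n_trees=50))
        table = importance_table(forest, small_dataset.gene_ids)
        assert table.loc[table["rank"] == 1, "gene_id"].item() == "g0"

    def test_never_split_gene_has_zero_importance(self, rng):
        n = 200
        y = (rng.random(n) < 0.5).astype(np.int64)
        X = np.stack([np.where(y == 1, 0.9, 0.1), np.full(n, 0.5)], axis=1)
        from cortexscreen.classifier import PixelDataset

        ds = PixelDataset(1, np.arange(n), np.zeros(n, dtype=np.int64), X, y, ["info", "const"])
        forest = train_forest(ds, np.arange(n), ForestConfig(n_trees=20, max_features=None))
        table = importance_table(forest, ds.gene_ids).set_index("gene_id")
        assert table.loc["const", "importance"] == 0.0
        assert table.loc["info", "rank"] == 1

    def test_no_split_forest_warns_uniform_zero(self):
        n = 50
        y = np.concatenate([np.ones(25, dtype=np.int64), np.zeros(25, dtype=np.int64)])
        X = np.full((n, 3), 0.5)
        from cortexscreen.classifier import PixelDataset

        ds = PixelDataset(1, np.arange(n), np.zeros(n, dtype=np.int64), X, y, ["a", "b", "c"])
        forest = train_forest(ds, np.arange(n), ForestConfig(n_trees=5))
        with pytest.warns(UserWarning, match="no splits"):
            table = importance_table(forest, ds.gene_ids)
        assert (table["importance"] == 0).all()

    def test_ties_rank_in_stable_gene_order(self):
        table = pd.DataFrame({"gene_id": ["a", "b"], "importance": [0.5, 0.5]})

        class FakeForest:
            feature_importances_ = np.array([0.5, 0.5])

        out = importance_table(FakeForest(), ["a", "b"])
        assert out.loc[out["gene_id"] == "a", "rank"].item() == 1

    def test_single_exhaustive_tree_matches_brute_force_gini(self, small_dataset):
        # dual-route check: sklearn's stored importances vs a from-scratch
        # re-partitioning of the data through the fitted tree
        config = ForestConfig(n_trees=1, bootstrap=False, max_features=None, random_state=0)
        forest = train_forest(small_dataset, np.arange(small_dataset.n_pixels), config)
        table = importance_table(forest, small_dataset.gene_ids)
        expected = brute_force_importances(
            forest.estimators_[0], small_dataset.X, small_dataset.y
        )
        np.testing.assert_allclose(table["importance"].to_numpy(), expected, atol=1e-9)


class TestImportanceHistogram:
    def test_counts_sum_to_gene_count(self, small_dataset):
        forest = train_forest(
            small_dataset, np.arange(small_dataset.n_pixels), ForestConfig(n_trees=30)
        )
        table = importance_table(forest, small_dataset.gene_ids)
        counts, edges = importance_histogram(table, n_bins=8)
        assert counts.sum() == len(table)
        assert len(edges) == len(counts) + 1

    def test_all_equal_importances_single_bin(self):
        table = pd.DataFrame({"gene_id": list("abcd"), "importance": [0.25] * 4})
        counts, edges = importance_histogram(table)
        assert (counts > 0).sum() == 1
        assert counts.sum() == 4

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="empty"):
            importance_histogram(pd.DataFrame({"gene_id": [], "importance": []}))
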