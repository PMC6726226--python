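"""Per-area pixel classification and Gini variable-importance ranking.

For one cortical area the workflow is: dilate the projected area mask to
define the surrounding region, assemble the N pixels × G genes luminance
matrix with binary inside/outside labels, hold out a fixed number of
randomly chosen test pixels, fit a Gini-criterion random forest, and report
the held-out confusion matrix plus the normalized per-gene importances.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from cortexscreen.projection import SurfaceProjection

CROSS_2D = ndimage.generate_binary_structure(2, 1)  # 4-connected cross


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters. Defaults: 100 Gini trees, random state 0,
    100 held-out test pixels, bootstrap resampling with sqrt(G) features
    considered per split."""

    n_trees: int = 100
    random_state: int = 0
    n_test_pixels: int = 100
    bootstrap: bool = True
    max_features: str | int | float | None = "sqrt"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_test_pixels < 1:
            raise ValueError("n_test_pixels must be >= 1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 held-out counts; class 1 = inside the area."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n_test(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_test

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn, "accuracy": self.accuracy}

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass
class PixelDataset:
    """N neighborhood pixels × G genes, with binary inside/outside labels."""

    area_id: int
    pixel_rows: np.ndarray
    pixel_cols: np.ndarray
    X: np.ndarray
    y: np.ndarray
    gene_ids: list[str]

    @property
    def n_pixels(self) -> int:
        return len(self.y)

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def export(self, prefix: str | os.PathLike) -> None:
        """Write features as .npz and labels/coordinates as CSV."""
        np.savez_compressed(f"{prefix}_features.npz", X=self.X, gene_ids=np.array(self.gene_ids))
        pd.DataFrame(
            {"row": self.pixel_rows, "col": self.pixel_cols, "label": self.y}
        ).to_csv(f"{prefix}_labels.csv", index=False)


def dilate_mask(
    mask2d: np.ndarray, iterations: int = 30, footprint: np.ndarray | None = None
) -> np.ndarray:
    """Iteratively dilate a binary mask with the 4-connected cross element.

    The result is intersected with *footprint* (the valid cortical pixels)
    when given, and always contains the input mask.
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    if not mask2d.any():
        raise ValueError("cannot dilate an empty mask (area absent from the projection)")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        out = mask2d.copy()
    else:
        out = ndimage.binary_dilation(mask2d, structure=CROSS_2D, iterations=iterations)
    if footprint is not None:
        out &= np.asarray(footprint, dtype=bool)
        out |= mask2d  # dilation must still contain the input
    return out


def build_pixel_dataset(
    projections: Sequence[SurfaceProjection],
    area_mask2d: np.ndarray,
    neighborhood: np.ndarray,
    area_id: int = 0,
) -> PixelDataset:
    """Assemble the N × G feature matrix for one area.

    Rows are the neighborhood pixels that are valid in every projection, in
    row-major order; the feature order is the order of *projections* (a
    stable, caller-stated gene order). Labels are 1 inside the area mask.
    """
    if not projections:
        raise ValueError("at least one projection is required")
    kinds = {p.kind for p in projections}
    if len(kinds) != 1:
        raise ValueError(f"all projections must share one kind, got {sorted(kinds)}")
    shape = projections[0].values.shape
    for p in projections:
        if p.values.shape != shape:
            raise ValueError("projections do not share one mapping")
    valid = np.ones(shape, dtype=bool)
    for p in projections:
        valid &= p.valid_mask
    sel = np.asarray(neighborhood, dtype=bool) & valid
    rows, cols = np.nonzero(sel)
    X = np.stack([p.values[rows, cols] for p in projections], axis=1)
    y = np.asarray(area_mask2d, dtype=bool)[rows, cols].astype(np.int64)
    return PixelDataset(
        area_id=area_id,
        pixel_rows=rows,
        pixel_cols=cols,
        X=X,
        y=y,
        gene_ids=[p.gene_id for p in projections],
    )


def split_train_test(
    dataset: PixelDataset, n_test: int = 100, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Hold out *n_test* pixels uniformly at random, without stratification.

    Returns disjoint, exhaustive (train, test) index arrays, deterministic
    given *seed*.
    """
    n = dataset.n_pixels
    if n <= n_test:
        raise ValueError(
            f"area {dataset.area_id}: {n} pixels is too small to hold out {n_test} test pixels"
        )
    train_idx, test_idx = train_test_split(
        np.arange(n), test_size=n_test, random_state=seed, shuffle=True, stratify=None
    )
    return np.sort(train_idx), np.sort(test_idx)


def train_forest(
    dataset: PixelDataset, train_idx: np.ndarray, config: ForestConfig = ForestConfig()
) -> RandomForestClassifier:
    """Fit the Gini-criterion random forest on the training pixels."""
    y_train = dataset.y[train_idx]
    if len(np.unique(y_train)) < 2:
        raise ValueError(
            f"area {dataset.area_id}: training set contains a single class; cannot fit a classifier"
        )
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        random_state=config.random_state,
        bootstrap=config.bootstrap,
        max_features=config.max_features,
        n_jobs=1,
    )
    forest.fit(dataset.X[train_idx], y_train)
    return forest


def evaluate(
    forest: RandomForestClassifier, dataset: PixelDataset, test_idx: np.ndarray
) -> ConfusionMatrix:
    """Confusion matrix over the held-out pixels (class 1 = inside)."""
    if len(test_idx) == 0:
        raise ValueError("test set is empty")
    y_true = dataset.y[test_idx]
    y_pred = forest.predict(dataset.X[test_idx])
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def importance_table(forest: RandomForestClassifier, gene_ids: Sequence[str]) -> pd.DataFrame:
    """Normalized Gini importances with ranks (1 = most important).

    Each split's impurity reduction (weighted by the fraction of samples
    reaching the node) is credited to its gene; totals are normalized to
    sum to 1 across all genes. Ties rank in stable gene order.
    """
    imp = np.asarray(forest.feature_importances_, dtype=np.float64)
    if len(imp) != len(gene_ids):
        raise ValueError("gene_ids length does not match the forest's feature count")
    total = imp.sum()
    if total <= 0:
        warnings.warn("forest contains no splits; importances are uniformly zero", stacklevel=2)
    else:
        imp = imp / total
    order = np.argsort(-imp, kind="stable")
    rank = np.empty(len(imp), dtype=np.int64)
    rank[order] = np.arange(1, len(imp) + 1)
    return pd.DataFrame({"gene_id": list(gene_ids), "importance": imp, "rank": rank})


def importance_histogram(table: pd.DataFrame, n_bins: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced histogram of importance values for reporting.

    Zero importances are counted in the lowest bin so counts always sum to
    the number of genes. Returns (counts, bin_edges) with len(edges) ==
    len(counts) + 1.
    """
    if len(table) == 0:
        raise ValueError("importance table is empty")
    imp = table["importance"].to_numpy(dtype=np.float64)
    positive = imp[imp > 0]
    if len(positive) == 0 or positive.min() == positive.max():
        # degenerate: one occupied bin
        center = positive.min() if len(positive) else 0.0
        edges = np.array([center, center + 1e-12])
        return np.array([len(imp)]), edges
    edges = np.geomspace(positive.min(), positive.max(), n_bins + 1)
    counts, edges = np.histogram(positive, bins=edges)
    counts[0] += int((imp <= 0).sum())
    return counts, edges
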