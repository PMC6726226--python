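"""Orchestrate the per-area marker screen and attach candidate flags.

The screen runs the full classifier pipeline for every area whose projected
mask is large enough, ranks genes by importance, and annotates the top
candidates with two automated flags that stand in for manual inspection:
hemisphere asymmetry of the border contrast, and a within-area planar
gradient. Flags only annotate candidates — they never remove them.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cortexscreen.classifier import (
    ConfusionMatrix,
    ForestConfig,
    build_pixel_dataset,
    dilate_mask,
    evaluate,
    importance_table,
    split_train_test,
    train_forest,
)
from cortexscreen.projection import AreaMask2D, SurfaceProjection

logger = logging.getLogger(__name__)

MIN_AREA_PIXELS = 1000


@dataclass(frozen=True)
class FlagResult:
    """Outcome of one automated inspection flag."""

    score: float
    flagged: bool
    applicable: bool = True

    def to_dict(self) -> dict:
        return {"score": self.score, "flagged": self.flagged, "applicable": self.applicable}


@dataclass
class CandidateGene:
    gene_id: str
    rank: int
    importance: float
    asymmetry: FlagResult
    gradient: FlagResult


@dataclass
class CandidateReport:
    """Screen output for one area: ranked candidates, flags and accuracy."""

    area_id: int
    candidates: list[CandidateGene]
    confusion: ConfusionMatrix
    pixel_count: int
    n_pixels: int  # dataset size (area + surrounding)

    @property
    def accuracy(self) -> float:
        return self.confusion.accuracy

    def to_dict(self) -> dict:
        return {
            "area_id": self.area_id,
            "pixel_count": self.pixel_count,
            "n_pixels": self.n_pixels,
            "accuracy": self.accuracy,
            "confusion": self.confusion.to_dict(),
            "candidates": [
                {
                    "gene_id": c.gene_id,
                    "rank": c.rank,
                    "importance": c.importance,
                    "asymmetry": c.asymmetry.to_dict(),
                    "gradient": c.gradient.to_dict(),
                }
                for c in self.candidates
            ],
        }


@dataclass(frozen=True)
class ScreenConfig:
    top_k: int = 10
    min_area_pixels: int = MIN_AREA_PIXELS
    dilate_iterations: int = 30
    forest: ForestConfig = field(default_factory=ForestConfig)
    split_seed: int = 0
    asymmetry_threshold: float = 0.5
    gradient_threshold: float = 0.5


def asymmetry_score(
    projection: SurfaceProjection,
    area_mask2d: np.ndarray,
    neighborhood: np.ndarray,
    midline_col: int,
    threshold: float = 0.5,
) -> FlagResult:
    """Difference of border contrast between hemispheres.

    Contrast per hemisphere is mean(inside) - mean(surrounding ring); the
    score is |left - right| / max(left, right). Not applicable when the
    area or its ring lies in a single hemisphere only.
    """
    area = np.asarray(area_mask2d, dtype=bool)
    ring = np.asarray(neighborhood, dtype=bool) & ~area
    vals = projection.values
    cols = np.arange(vals.shape[1])
    left = cols[None, :] < midline_col
    right = cols[None, :] >= midline_col
    contrasts = []
    for hemi in (left, right):
        inside = area & hemi & np.isfinite(vals)
        outside = ring & hemi & np.isfinite(vals)
        if not inside.any() or not outside.any():
            return FlagResult(score=float("nan"), flagged=False, applicable=False)
        contrasts.append(float(vals[inside].mean() - vals[outside].mean()))
    denom = max(contrasts)
    if denom <= 1e-12:
        return FlagResult(score=float("nan"), flagged=False, applicable=False)
    score = abs(contrasts[0] - contrasts[1]) / denom
    return FlagResult(score=score, flagged=score > threshold)


def gradient_score(
    projection: SurfaceProjection,
    area_mask2d: np.ndarray,
    threshold: float = 0.5,
    min_pixels: int = 100,
) -> FlagResult:
    """Fraction of within-area variance explained by a least-squares plane.

    R^2 of the fit luminance ~ 1 + row + col over the area's valid pixels;
    constant expression scores 0, a pure linear ramp scores 1.
    """
    area = np.asarray(area_mask2d, dtype=bool) & projection.valid_mask
    rows, cols = np.nonzero(area)
    if len(rows) < min_pixels:
        return FlagResult(score=float("nan"), flagged=False, applicable=False)
    v = projection.values[rows, cols]
    ss_tot = float(((v - v.mean()) ** 2).sum())
    if ss_tot <= 1e-15:
        return FlagResult(score=0.0, flagged=False)
    design = np.stack([np.ones_like(rows, dtype=np.float64), rows, cols], axis=1)
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    resid = v - design @ coef
    score = 1.0 - float((resid**2).sum()) / ss_tot
    score = float(np.clip(score, 0.0, 1.0))
    return FlagResult(score=score, flagged=score > threshold)


def run_screen(
    projections: Sequence[SurfaceProjection],
    area_masks: Mapping[int, AreaMask2D],
    config: ScreenConfig = ScreenConfig(),
) -> list[CandidateReport]:
    """Run the classifier pipeline for every sufficiently large area.

    Areas whose projected mask occupies fewer than ``config.min_area_pixels``
    pixels are excluded (logged, not an error). Raises if no area survives.
    """
    if not projections:
        raise ValueError("no projections supplied")
    valid = np.ones(projections[0].values.shape, dtype=bool)
    for p in projections:
        valid &= p.valid_mask
    proj_by_gene = {p.gene_id: p for p in projections}
    midline_col = projections[0].midline_col

    reports: list[CandidateReport] = []
    for area_id, amask in area_masks.items():
        if amask.pixel_count < config.min_area_pixels:
            logger.info(
                "area %s excluded: %d projected pixels < %d",
                area_id,
                amask.pixel_count,
                config.min_area_pixels,
            )
            continue
        neighborhood = dilate_mask(amask.mask, iterations=config.dilate_iterations, footprint=valid)
        dataset = build_pixel_dataset(projections, amask.mask, neighborhood, area_id=area_id)
        train_idx, test_idx = split_train_test(
            dataset, n_test=config.forest.n_test_pixels, seed=config.split_seed
        )
        forest = train_forest(dataset, train_idx, config.forest)
        confusion = evaluate(forest, dataset, test_idx)
        table = importance_table(forest, dataset.gene_ids)
        top = table.sort_values("rank").head(config.top_k)
        candidates = []
        for row in top.itertuples():
            proj = proj_by_gene[row.gene_id]
            candidates.append(
                CandidateGene(
                    gene_id=row.gene_id,
                    rank=int(row.rank),
                    importance=float(row.importance),
                    asymmetry=asymmetry_score(
                        proj, amask.mask, neighborhood, midline_col, config.asymmetry_threshold
                    ),
                    gradient=gradient_score(proj, amask.mask, config.gradient_threshold),
                )
            )
        reports.append(
            CandidateReport(
                area_id=area_id,
                candidates=candidates,
                confusion=confusion,
                pixel_count=amask.pixel_count,
                n_pixels=dataset.n_pixels,
            )
        )
    if not reports:
        raise ValueError(
            f"no area passed the size filter (min_area_pixels={config.min_area_pixels})"
        )
    return reports


def accuracy_vs_size_report(reports: Sequence[CandidateReport]) -> pd.DataFrame:
    """(area, projected pixel count, held-out accuracy) rows for plotting."""
    if len(reports) < 2:
        raise ValueError("need at least two area reports")
    return pd.DataFrame(
        [
            {"area_id": r.area_id, "pixel_count": r.pixel_count, "accuracy": r.accuracy}
            for r in reports
        ]
    )


def reports_to_csv(reports: Sequence[CandidateReport], path: str | os.PathLike) -> None:
    rows = []
    for r in reports:
        for c in r.candidates:
            rows.append(
                {
                    "area_id": r.area_id,
                    "gene_id": c.gene_id,
                    "rank": c.rank,
                    "importance": c.importance,
                    "accuracy": r.accuracy,
                    "area_pixel_count": r.pixel_count,
                    "asymmetry_score": c.asymmetry.score,
                    "asymmetry_flag": c.asymmetry.flagged,
                    "gradient_score": c.gradient.score,
                    "gradient_flag": c.gradient.flagged,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def reports_to_json(reports: Sequence[CandidateReport], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=1)
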