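"""Collapse masked 3D volumes to 2D surface maps.

A :class:`SurfaceMapping` is built once per cortex mask and reused for every
gene and every area mask, guaranteeing that expression maps and area borders
stay aligned. For each outer-surface voxel a straight path is traced inward
along the estimated surface normal (unit steps, nearest-voxel sampling)
until it leaves the mask; a 2D pixel's value is the maximum along its path.

Two output geometries are supported:

``top``
    Each path lands on the (AP, ML) pixel of its surface voxel; where
    several surface voxels share a horizontal pixel the shallowest
    (most dorsal) one wins, mimicking a view from above.
``flatmap``
    Per coronal section, the pial contour is ordered by angle and unfurled:
    each contour pixel maps to (AP index, signed position along the contour
    from the dorsal midline), measured in contour-pixel steps.

Surface normals are estimated from the gradient of the Euclidean distance
transform of the mask (lightly smoothed), which is parameter-free and valid
for any shell-like mask.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from cortexscreen.atlas import ExpressionVolume

INVALID = np.nan
_EPS = 1e-9


class EmptyMappingError(ValueError):
    """Raised when a cortex mask has no identifiable outer surface."""


@dataclass
class SurfaceMapping:
    """Pixel -> projection-path lookup shared by all genes of a study.

    ``path_voxels`` holds raveled voxel indices of every path back to back;
    path *p* spans ``path_voxels[path_starts[p]:path_starts[p+1]]`` and its
    first entry is the surface voxel. ``midline_col`` is the 2D column of
    the dorsal midline, used to split hemispheres.
    """

    kind: str
    grid_shape: tuple[int, int, int]
    shape2d: tuple[int, int]
    midline_col: int
    pixel_rows: np.ndarray
    pixel_cols: np.ndarray
    path_starts: np.ndarray
    path_voxels: np.ndarray

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_rows)

    @property
    def valid_mask(self) -> np.ndarray:
        out = np.zeros(self.shape2d, dtype=bool)
        out[self.pixel_rows, self.pixel_cols] = True
        return out

    @property
    def surface_voxels(self) -> np.ndarray:
        """Raveled index of the surface voxel of each path."""
        return self.path_voxels[self.path_starts[:-1]]

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "kind": self.kind,
            "grid_shape": list(self.grid_shape),
            "shape2d": list(self.shape2d),
            "midline_col": int(self.midline_col),
            "pixel_rows": self.pixel_rows.tolist(),
            "pixel_cols": self.pixel_cols.tolist(),
            "path_starts": self.path_starts.tolist(),
            "path_voxels": self.path_voxels.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SurfaceMapping":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            kind=payload["kind"],
            grid_shape=tuple(payload["grid_shape"]),
            shape2d=tuple(payload["shape2d"]),
            midline_col=int(payload["midline_col"]),
            pixel_rows=np.asarray(payload["pixel_rows"], dtype=np.int64),
            pixel_cols=np.asarray(payload["pixel_cols"], dtype=np.int64),
            path_starts=np.asarray(payload["path_starts"], dtype=np.int64),
            path_voxels=np.asarray(payload["path_voxels"], dtype=np.int64),
        )


@dataclass
class SurfaceProjection:
    """2D luminance map; invalid pixels (no projection path) are NaN."""

    kind: str
    values: np.ndarray
    gene_id: str = ""
    midline_col: int = 0

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class AreaMask2D:
    """Projected binary area mask, nonzero only on valid mapping pixels."""

    area_id: int
    mask: np.ndarray
    kind: str = "top"

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def _slice_contour(mask2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Outer-contour pixels of one coronal slice, in dorsal-anchored order.

    A boundary pixel belongs to the pial (outer) contour iff the ray from
    the slice centroid through the pixel leaves the slice without striking
    the mask again, i.e. the pixel is radially visible from outside. This
    assumes slice masks are star-shaped about their centroid, which holds
    for shell and slab geometries. Returns (pixels (C,2), signed arc
    positions (C,) in contour-pixel steps from the dorsal midline).
    """
    n_dv, n_ml = mask2d.shape
    eroded = ndimage.binary_erosion(mask2d, structure=ndimage.generate_binary_structure(2, 1))
    bj, bk = np.nonzero(mask2d & ~eroded)
    if len(bj) == 0:
        return np.empty((0, 2), dtype=np.int64), np.empty(0, dtype=np.int64)
    jc, kc = ndimage.center_of_mass(mask2d)

    dirs = np.stack([bj - jc, bk - kc], axis=1)
    nrm = np.linalg.norm(dirs, axis=1)
    nrm[nrm < _EPS] = 1.0
    dirs = dirs / nrm[:, None]

    steps = np.arange(0.0, n_dv + n_ml, 0.5)
    pj = np.rint(bj[:, None] + dirs[:, 0:1] * steps[None, :]).astype(np.int64)
    pk = np.rint(bk[:, None] + dirs[:, 1:2] * steps[None, :]).astype(np.int64)
    inb = (pj >= 0) & (pj < n_dv) & (pk >= 0) & (pk < n_ml)
    hit = np.zeros(pj.shape, dtype=bool)
    hit[inb] = mask2d[pj[inb], pk[inb]]
    blocked = (hit & (steps[None, :] > 1.5)).any(axis=1)
    outer = ~blocked
    oj, ok = bj[outer], bk[outer]
    if len(oj) == 0:
        return np.empty((0, 2), dtype=np.int64), np.empty(0, dtype=np.int64)

    # order around the slice centroid; wrap so the open arc is monotone
    alpha = np.arctan2(jc - oj, ok - kc)
    alpha = np.where(alpha < -np.pi / 2, alpha + 2 * np.pi, alpha)
    order = np.argsort(alpha, kind="stable")
    oj, ok, alpha = oj[order], ok[order], alpha[order]
    anchor = int(np.argmin(np.abs(alpha - np.pi / 2)))
    arc = np.arange(len(oj)) - anchor
    return np.stack([oj, ok], axis=1), arc


def build_surface_mapping(cortex_mask: np.ndarray, kind: str = "top") -> SurfaceMapping:
    """Trace projection paths from the outer surface of *cortex_mask*.

    The mapping depends on the mask only — it is shared by every gene.
    """
    if kind not in ("top", "flatmap"):
        raise ValueError(f"unknown projection kind {kind!r}")
    mask = np.asarray(cortex_mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("cortex mask must be 3D")
    if not mask.any():
        raise EmptyMappingError("cortex mask is empty; no surface to project from")

    n_ap, n_dv, n_ml = mask.shape
    dist = ndimage.distance_transform_edt(mask)
    smooth = ndimage.gaussian_filter(dist, sigma=1.0)
    grad = np.gradient(smooth)  # points inward (toward deeper tissue)

    max_len = n_dv + n_ml
    tvals = np.arange(max_len, dtype=np.float64)

    entries: list[tuple[int, int, int, np.ndarray]] = []  # (ap, col_key, surface_j, path)
    anchors_k: list[int] = []
    for i in range(n_ap):
        m = mask[i]
        if not m.any():
            continue
        contour, arc = _slice_contour(m)
        if len(contour) == 0:
            continue
        anchor_idx = int(np.nonzero(arc == 0)[0][0])
        anchors_k.append(int(contour[anchor_idx, 1]))

        sj, sk = contour[:, 0], contour[:, 1]
        d = np.stack([grad[0][i, sj, sk], grad[1][i, sj, sk], grad[2][i, sj, sk]], axis=1)
        nrm = np.linalg.norm(d, axis=1)
        nrm[nrm < _EPS] = 1.0
        d /= nrm[:, None]

        pi_ = np.rint(i + d[:, 0:1] * tvals[None, :]).astype(np.int64)
        pj = np.rint(sj[:, None] + d[:, 1:2] * tvals[None, :]).astype(np.int64)
        pk = np.rint(sk[:, None] + d[:, 2:3] * tvals[None, :]).astype(np.int64)
        inb = (pi_ >= 0) & (pi_ < n_ap) & (pj >= 0) & (pj < n_dv) & (pk >= 0) & (pk < n_ml)
        alive = np.zeros(pi_.shape, dtype=bool)
        alive[inb] = mask[pi_[inb], pj[inb], pk[inb]]
        alive = np.cumprod(alive, axis=1).astype(bool)
        lengths = alive.sum(axis=1)

        flat = (pi_ * n_dv + pj) * n_ml + pk
        for p in range(len(sj)):
            path = flat[p, : lengths[p]]
            # drop consecutive duplicate voxels from nearest-voxel rounding
            keep = np.ones(len(path), dtype=bool)
            keep[1:] = path[1:] != path[:-1]
            path = path[keep]
            col_key = int(sk[p]) if kind == "top" else int(arc[p])
            entries.append((i, col_key, int(sj[p]), path))

    if not entries:
        raise EmptyMappingError("no outer-surface voxels found")

    if kind == "top":
        best: dict[tuple[int, int], tuple[int, np.ndarray]] = {}
        for ap, col, sj, path in entries:
            cur = best.get((ap, col))
            if cur is None or sj < cur[0]:  # shallowest surface voxel wins
                best[(ap, col)] = (sj, path)
        pixels = sorted(best)
        rows = np.array([p[0] for p in pixels], dtype=np.int64)
        cols = np.array([p[1] for p in pixels], dtype=np.int64)
        paths = [best[p][1] for p in pixels]
        shape2d = (n_ap, n_ml)
        midline_col = int(np.median(anchors_k))
    else:
        arcs = np.array([e[1] for e in entries])
        offset = int(-arcs.min())
        width = int(arcs.max()) + offset + 1
        order = np.lexsort((arcs, [e[0] for e in entries]))
        rows = np.array([entries[o][0] for o in order], dtype=np.int64)
        cols = np.array([entries[o][1] + offset for o in order], dtype=np.int64)
        paths = [entries[o][3] for o in order]
        shape2d = (n_ap, width)
        midline_col = offset

    starts = np.zeros(len(paths) + 1, dtype=np.int64)
    starts[1:] = np.cumsum([len(p) for p in paths])
    voxels = np.concatenate(paths) if paths else np.empty(0, dtype=np.int64)
    return SurfaceMapping(
        kind=kind,
        grid_shape=mask.shape,
        shape2d=shape2d,
        midline_col=midline_col,
        pixel_rows=rows,
        pixel_cols=cols,
        path_starts=starts,
        path_voxels=voxels,
    )


def project_volume(volume: ExpressionVolume, mapping: SurfaceMapping) -> SurfaceProjection:
    """Maximum-intensity projection of *volume* along each mapping path."""
    if volume.values.shape != mapping.grid_shape:
        raise ValueError(
            f"volume shape {volume.values.shape} does not match mapping lattice {mapping.grid_shape}"
        )
    flat = volume.values.ravel()
    samples = flat[mapping.path_voxels]
    pix = np.maximum.reduceat(samples, mapping.path_starts[:-1])
    out = np.full(mapping.shape2d, INVALID, dtype=np.float64)
    out[mapping.pixel_rows, mapping.pixel_cols] = pix
    return SurfaceProjection(kind=mapping.kind, values=out, gene_id=volume.gene_id, midline_col=mapping.midline_col)


def project_area_mask(
    area_mask3d: np.ndarray,
    mapping: SurfaceMapping,
    area_id: int = 0,
    labels3d: np.ndarray | None = None,
) -> AreaMask2D:
    """Project a 3D area mask with the same mapping used for expression.

    A pixel is inside iff its path's surface voxel is inside the area. Where
    an annotation is supplied and the surface voxel is unlabeled, the
    majority vote along the path decides instead.
    """
    area_mask3d = np.asarray(area_mask3d, dtype=bool)
    if area_mask3d.shape != mapping.grid_shape:
        raise ValueError(
            f"mask shape {area_mask3d.shape} does not match mapping lattice {mapping.grid_shape}"
        )
    flat = area_mask3d.ravel()
    surf = mapping.surface_voxels
    inside = flat[surf]
    if labels3d is not None:
        unlabeled = np.asarray(labels3d).ravel()[surf] == 0
        if unlabeled.any():
            in_path = np.add.reduceat(flat[mapping.path_voxels].astype(np.int64), mapping.path_starts[:-1])
            lengths = np.diff(mapping.path_starts)
            majority = in_path * 2 > lengths
            inside = np.where(unlabeled, majority, inside)
    out = np.zeros(mapping.shape2d, dtype=bool)
    out[mapping.pixel_rows[inside], mapping.pixel_cols[inside]] = True
    mask2d = AreaMask2D(area_id=area_id, mask=out, kind=mapping.kind)
    if mask2d.pixel_count == 0:
        warnings.warn(f"area {area_id} projects to zero pixels (occluded or absent)", stacklevel=2)
    return mask2d
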