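"""Data model for co-registered volumes, the structure hierarchy, and masks.

All volumes in a study share one voxel lattice with 0-based indexing and
axis order (anterior-posterior, dorsal-ventral, medial-lateral). Coronal
sections are planes of constant AP index.
"""

from __future__ import annotations

import abc
import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from cortexscreen.formats import read_nrrd, write_nrrd

DEFAULT_VOXEL_SIZE_UM = 200.0


@dataclass
class ExpressionVolume:
    """Per-gene 3D luminance grid, normalized to [0, 1]."""

    gene_id: str
    values: np.ndarray
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expression volume must be 3D, got shape {self.values.shape}")
        vmin, vmax = float(self.values.min()), float(self.values.max())
        if vmin < 0.0 or vmax > 1.0:
            raise ValueError(f"expression values must lie in [0, 1]; got range [{vmin}, {vmax}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def to_nrrd(self, path: str | os.PathLike) -> None:
        write_nrrd(path, self.values.astype(np.float32), voxel_size_um=self.voxel_size_um)

    @classmethod
    def from_nrrd(cls, path: str | os.PathLike, gene_id: str | None = None) -> "ExpressionVolume":
        values, fields = read_nrrd(path)
        spacing = DEFAULT_VOXEL_SIZE_UM
        if "spacings" in fields:
            spacing = float(fields["spacings"].split()[0])
        if gene_id is None:
            gene_id = os.path.splitext(os.path.basename(path))[0]
        return cls(gene_id=gene_id, values=np.asarray(values, dtype=np.float64), voxel_size_um=spacing)


@dataclass
class AnnotationVolume:
    """Integer structure labels per voxel; 0 is reserved for background."""

    labels: np.ndarray
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"annotation volume must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("annotation labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("annotation labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def to_nrrd(self, path: str | os.PathLike) -> None:
        write_nrrd(path, self.labels.astype(np.int32), voxel_size_um=self.voxel_size_um)

    @classmethod
    def from_nrrd(cls, path: str | os.PathLike) -> "AnnotationVolume":
        labels, fields = read_nrrd(path)
        spacing = DEFAULT_VOXEL_SIZE_UM
        if "spacings" in fields:
            spacing = float(fields["spacings"].split()[0])
        return cls(labels=labels.astype(np.int64), voxel_size_um=spacing)


@dataclass(frozen=True)
class StructureNode:
    id: int
    name: str
    parent_id: int | None


class StructureTree:
    """Acyclic hierarchy of brain structures with a designated cortex root.

    Masks are derived by descendant queries: a voxel belongs to a structure
    if its label equals the structure id or any descendant id.
    """

    def __init__(self, nodes: Iterable[StructureNode], cortex_root_id: int):
        self._nodes: dict[int, StructureNode] = {}
        for node in nodes:
            if node.id in self._nodes:
                raise ValueError(f"duplicate structure id {node.id}")
            self._nodes[node.id] = node
        if cortex_root_id not in self._nodes:
            raise KeyError(f"cortex_root_id {cortex_root_id} not present in tree")
        self.cortex_root_id = cortex_root_id
        self._children: dict[int, list[int]] = {nid: [] for nid in self._nodes}
        for node in self._nodes.values():
            if node.parent_id is not None:
                if node.parent_id not in self._nodes:
                    raise ValueError(f"node {node.id} references missing parent {node.parent_id}")
                self._children[node.parent_id].append(node.id)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for nid in self._nodes:
            seen = set()
            cur: int | None = nid
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"structure tree contains a cycle through node {cur}")
                seen.add(cur)
                cur = self._nodes[cur].parent_id

    def __contains__(self, structure_id: int) -> bool:
        return structure_id in self._nodes

    def __iter__(self) -> Iterator[StructureNode]:
        return iter(self._nodes.values())

    def node(self, structure_id: int) -> StructureNode:
        try:
            return self._nodes[structure_id]
        except KeyError:
            raise KeyError(f"unknown structure id {structure_id}") from None

    def children(self, structure_id: int) -> list[int]:
        self.node(structure_id)
        return list(self._children[structure_id])

    def descendants(self, structure_id: int) -> set[int]:
        """All ids in the subtree rooted at *structure_id*, inclusive."""
        self.node(structure_id)
        out: set[int] = set()
        stack = [structure_id]
        while stack:
            cur = stack.pop()
            out.add(cur)
            stack.extend(self._children[cur])
        return out

    def is_descendant(self, structure_id: int, ancestor_id: int) -> bool:
        cur: int | None = structure_id
        while cur is not None:
            if cur == ancestor_id:
                return True
            cur = self._nodes[cur].parent_id
        return False

    def leaf_areas(self, root_id: int | None = None) -> list[int]:
        """Leaves of the subtree rooted at *root_id* (default: cortex root)."""
        root = self.cortex_root_id if root_id is None else root_id
        return sorted(nid for nid in self.descendants(root) if not self._children[nid])

    # ---- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": n.id, "name": n.name, "parent_id": -1 if n.parent_id is None else n.parent_id}
            for n in sorted(self._nodes.values(), key=lambda n: n.id)
        ]
        return pd.DataFrame(rows, columns=["id", "name", "parent_id"])

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "cortex_root_id": self.cortex_root_id,
            "nodes": self.to_frame().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "StructureTree":
        with open(path) as fh:
            payload = json.load(fh)
        nodes = [
            StructureNode(
                id=int(r["id"]),
                name=str(r["name"]),
                parent_id=None if int(r["parent_id"]) < 0 else int(r["parent_id"]),
            )
            for r in payload["nodes"]
        ]
        return cls(nodes, cortex_root_id=int(payload["cortex_root_id"]))

    @classmethod
    def from_csv(cls, path: str | os.PathLike, cortex_root_id: int) -> "StructureTree":
        frame = pd.read_csv(path)
        nodes = [
            StructureNode(
                id=int(r.id),
                name=str(r.name),
                parent_id=None if int(r.parent_id) < 0 else int(r.parent_id),
            )
            for r in frame.itertuples()
        ]
        return cls(nodes, cortex_root_id=cortex_root_id)


def cortex_mask(annotation: AnnotationVolume, tree: StructureTree) -> np.ndarray:
    """Binary mask: voxel is True iff its label is the cortex root or a descendant."""
    ids = np.fromiter(tree.descendants(tree.cortex_root_id), dtype=np.int64)
    return np.isin(annotation.labels, ids)


def area_mask(annotation: AnnotationVolume, tree: StructureTree, area_id: int) -> np.ndarray:
    """Binary mask of one area (the label itself plus any descendant labels).

    An area absent from the volume yields an all-zero mask with a warning
    rather than an error, so screens over full area lists degrade gracefully.
    """
    ids = np.fromiter(tree.descendants(area_id), dtype=np.int64)
    mask = np.isin(annotation.labels, ids)
    if not mask.any():
        warnings.warn(f"area {area_id} has no voxels in the annotation volume", stacklevel=2)
    return mask


def mask_volume(volume: ExpressionVolume, mask: np.ndarray) -> ExpressionVolume:
    """Elementwise product of a volume with a (binary) mask."""
    mask = np.asarray(mask)
    if mask.shape != volume.values.shape:
        raise ValueError(f"mask shape {mask.shape} does not match volume shape {volume.values.shape}")
    return ExpressionVolume(
        gene_id=volume.gene_id,
        values=volume.values * mask.astype(np.float64),
        voxel_size_um=volume.voxel_size_um,
    )


class AtlasProvider(abc.ABC):
    """Source of co-registered volumes and the structure hierarchy.

    The shipped implementation is :class:`cortexscreen.synthetic.SyntheticAtlasProvider`;
    an adapter backed by an external atlas API can implement the same surface.
    """

    @abc.abstractmethod
    def annotation(self) -> AnnotationVolume: ...

    @abc.abstractmethod
    def structure_tree(self) -> StructureTree: ...

    @abc.abstractmethod
    def gene_ids(self) -> Sequence[str]: ...

    @abc.abstractmethod
    def expression(self, gene_id: str) -> ExpressionVolume: ...
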