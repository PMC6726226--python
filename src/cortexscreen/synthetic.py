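"""Synthetic volumes with the statistical structure the marker screen assumes.

The geometry is a half-cylindrical cortical shell whose axis runs along the
anterior-posterior (AP) axis, so coronal sections are planes of constant AP
index. The shell is partitioned into contiguous areas defined as angular ×
AP sectors; area borders are therefore radial, i.e. perpendicular to the
local surface tangent. Gene volumes plant expression steps at area borders,
smooth gradients, per-section multiplicative banding and zeroed coronal
sections (missing data), all deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from cortexscreen.atlas import (
    AnnotationVolume,
    AtlasProvider,
    ExpressionVolume,
    StructureNode,
    StructureTree,
    area_mask,
    cortex_mask,
)

ROOT_ID = 1
CORTEX_ID = 2
SUBCORTICAL_ID = 3
AREA_ID_BASE = 10

GeneKind = Literal["border_marker", "gradient", "uniform", "noise_only"]

#: (phi_lo, phi_hi, ap_lo, ap_hi) fractional bounds of one area sector.
Sector = tuple[float, float, float, float]


@dataclass(frozen=True)
class NoiseSpec:
    """Acquisition artifacts applied to every gene volume.

    missing_band_probability
        Per-coronal-section probability that the whole section is zeroed.
    banding_factor_range
        Interval for the per-section multiplicative luminance factor.
    background_level
        Luminance assigned to subcortical (non-shell tissue) voxels.
    """

    missing_band_probability: float = 0.0
    banding_factor_range: tuple[float, float] = (1.0, 1.0)
    background_level: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.missing_band_probability <= 1.0:
            raise ValueError("noise.missing_band_probability must lie in [0, 1]")
        lo, hi = self.banding_factor_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("noise.banding_factor_range must be a positive interval (lo <= hi)")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("noise.background_level must lie in [0, 1]")


@dataclass(frozen=True)
class GeneSpec:
    """One synthetic gene.

    Kinds:
      * ``border_marker(target_area, inside_level, outside_level)`` — abrupt
        step at the target area's border. ``inside_level_right``, when set,
        replaces ``inside_level`` in the right hemisphere (ML index above
        the midline), producing a hemisphere-asymmetric marker.
      * ``gradient(axis, low, high)`` — linear ramp across the shell along a
        lattice axis.
      * ``uniform(level)`` — constant expression over the shell.
      * ``noise_only`` — zero signal; only additive noise and artifacts.
    """

    gene_id: str
    kind: GeneKind
    noise_sd: float = 0.0
    target_area: int | None = None
    inside_level: float | None = None
    outside_level: float | None = None
    inside_level_right: float | None = None
    axis: int = 0
    low: float = 0.0
    high: float = 1.0
    level: float = 0.0

    @classmethod
    def border_marker(
        cls,
        gene_id: str,
        target_area: int,
        inside_level: float,
        outside_level: float,
        noise_sd: float = 0.0,
        inside_level_right: float | None = None,
    ) -> "GeneSpec":
        return cls(
            gene_id=gene_id,
            kind="border_marker",
            target_area=target_area,
            inside_level=inside_level,
            outside_level=outside_level,
            inside_level_right=inside_level_right,
            noise_sd=noise_sd,
        )

    @classmethod
    def gradient(cls, gene_id: str, axis: int, low: float, high: float, noise_sd: float = 0.0) -> "GeneSpec":
        return cls(gene_id=gene_id, kind="gradient", axis=axis, low=low, high=high, noise_sd=noise_sd)

    @classmethod
    def uniform(cls, gene_id: str, level: float, noise_sd: float = 0.0) -> "GeneSpec":
        return cls(gene_id=gene_id, kind="uniform", level=level, noise_sd=noise_sd)

    @classmethod
    def noise_only(cls, gene_id: str, noise_sd: float) -> "GeneSpec":
        return cls(gene_id=gene_id, kind="noise_only", noise_sd=noise_sd)

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"gene {self.gene_id}: noise_sd must be non-negative")
        if self.kind == "border_marker":
            if self.target_area is None:
                raise ValueError(f"gene {self.gene_id}: border_marker requires target_area")
            levels = [self.inside_level, self.outside_level]
            if self.inside_level_right is not None:
                levels.append(self.inside_level_right)
            for lv in levels:
                if lv is None or not 0.0 <= lv <= 1.0:
                    raise ValueError(f"gene {self.gene_id}: marker levels must lie in [0, 1]")
            if self.inside_level == self.outside_level:
                raise ValueError(f"gene {self.gene_id}: inside_level must differ from outside_level")
        elif self.kind == "gradient":
            if self.axis not in (0, 1, 2):
                raise ValueError(f"gene {self.gene_id}: gradient axis must be 0, 1 or 2")
            for lv in (self.low, self.high):
                if not 0.0 <= lv <= 1.0:
                    raise ValueError(f"gene {self.gene_id}: gradient levels must lie in [0, 1]")
        elif self.kind == "uniform":
            if not 0.0 <= self.level <= 1.0:
                raise ValueError(f"gene {self.gene_id}: level must lie in [0, 1]")
        elif self.kind != "noise_only":
            raise ValueError(f"gene {self.gene_id}: unknown kind {self.kind!r}")


def default_layout(n_areas: int, n_ap_bands: int | None = None) -> list[Sector]:
    """Tile the shell into ``n_areas`` angular × AP sectors.

    The AP band count defaults to the largest divisor of ``n_areas`` not
    exceeding its square root, giving near-square sectors.
    """
    if n_areas < 1:
        raise ValueError("n_areas must be >= 1")
    if n_ap_bands is None:
        n_ap_bands = max(d for d in range(1, int(math.isqrt(n_areas)) + 1) if n_areas % d == 0)
    if n_areas % n_ap_bands != 0:
        raise ValueError(f"n_ap_bands={n_ap_bands} does not divide n_areas={n_areas}")
    n_phi = n_areas // n_ap_bands
    sectors: list[Sector] = []
    for a in range(n_ap_bands):
        for p in range(n_phi):
            sectors.append((p / n_phi, (p + 1) / n_phi, a / n_ap_bands, (a + 1) / n_ap_bands))
    return sectors


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study."""

    grid_shape: tuple[int, int, int] = (80, 30, 60)
    shell_inner_radius: float = 20.0
    shell_thickness: float = 6.0
    n_areas: int = 4
    area_seed_layout: list[Sector] | None = None
    gene_specs: list[GeneSpec] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    rng_seed: int = 0
    mirror: bool = False
    voxel_size_um: float = 200.0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive voxel counts")
        if self.shell_thickness < 2:
            raise ValueError("shell_thickness must be >= 2 voxels")
        if self.shell_inner_radius <= 0:
            raise ValueError("shell_inner_radius must be positive")
        if self.n_areas < 1:
            raise ValueError("n_areas must be >= 1")
        n_ap, n_dv, n_ml = self.grid_shape
        outer = self.shell_inner_radius + self.shell_thickness
        if outer > min(n_dv - 1, (n_ml - 1) / 2.0) + 0.5:
            raise ValueError(
                f"grid_shape {self.grid_shape} too small for shell of outer radius {outer}"
            )
        layout = self.layout()
        if len(layout) != self.n_areas:
            raise ValueError("area_seed_layout length must equal n_areas")
        self.noise.validate()
        for gene in self.gene_specs:
            gene.validate()

    def layout(self) -> list[Sector]:
        return default_layout(self.n_areas) if self.area_seed_layout is None else list(self.area_seed_layout)

    def area_ids(self) -> list[int]:
        return [AREA_ID_BASE + i for i in range(self.n_areas)]

    # ---- config round-trip (CLI) --------------------------------------
    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "shell_inner_radius": self.shell_inner_radius,
            "shell_thickness": self.shell_thickness,
            "n_areas": self.n_areas,
            "area_seed_layout": None if self.area_seed_layout is None else [list(s) for s in self.area_seed_layout],
            "genes": [
                {k: v for k, v in vars(g).items() if v is not None}
                for g in self.gene_specs
            ],
            "noise": {
                "missing_band_probability": self.noise.missing_band_probability,
                "banding_factor_range": list(self.noise.banding_factor_range),
                "background_level": self.noise.background_level,
            },
            "rng_seed": self.rng_seed,
            "mirror": self.mirror,
            "voxel_size_um": self.voxel_size_um,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SyntheticSpec":
        noise_cfg = dict(payload.get("noise", {}))
        if "banding_factor_range" in noise_cfg:
            noise_cfg["banding_factor_range"] = tuple(noise_cfg["banding_factor_range"])
        genes = [GeneSpec(**g) for g in payload.get("genes", [])]
        layout = payload.get("area_seed_layout")
        spec = cls(
            grid_shape=tuple(payload.get("grid_shape", (80, 30, 60))),
            shell_inner_radius=payload.get("shell_inner_radius", 20.0),
            shell_thickness=payload.get("shell_thickness", 6.0),
            n_areas=payload.get("n_areas", 4),
            area_seed_layout=None if layout is None else [tuple(s) for s in layout],
            gene_specs=genes,
            noise=NoiseSpec(**noise_cfg),
            rng_seed=payload.get("rng_seed", 0),
            mirror=payload.get("mirror", False),
            voxel_size_um=payload.get("voxel_size_um", 200.0),
        )
        spec.validate()
        return spec


def _shell_geometry(spec: SyntheticSpec):
    """Per-voxel radius and angle of the half-cylindrical shell.

    Returns (shell, cavity, phi) where ``phi`` runs from 0 at one lateral
    edge through pi/2 at the dorsal midline to pi at the other edge.
    """
    n_ap, n_dv, n_ml = spec.grid_shape
    j0 = n_dv - 1
    k0 = (n_ml - 1) / 2.0
    jj, kk = np.meshgrid(np.arange(n_dv), np.arange(n_ml), indexing="ij")
    dj = j0 - jj  # height above the ventral base plane
    dk = kk - k0
    radius = np.hypot(dj, dk)
    outer = spec.shell_inner_radius + spec.shell_thickness
    shell2d = (radius >= spec.shell_inner_radius) & (radius < outer)
    cavity2d = radius < spec.shell_inner_radius
    phi2d = np.arctan2(dj, dk)
    return shell2d, cavity2d, phi2d


def generate_annotation(spec: SyntheticSpec) -> tuple[AnnotationVolume, StructureTree]:
    """Label the shell with contiguous area sectors and build the hierarchy.

    Every shell voxel carries exactly one area label (child of the cortex
    node); cavity voxels are labeled subcortical; the rest is background 0.
    Deterministic: the geometry is a pure function of the spec.
    """
    spec.validate()
    n_ap, n_dv, n_ml = spec.grid_shape
    shell2d, cavity2d, phi2d = _shell_geometry(spec)

    if spec.mirror:
        # fold about the dorsal midline: 0 at midline, 1 at lateral edges
        phi_frac2d = np.abs(phi2d - np.pi / 2.0) / (np.pi / 2.0)
    else:
        phi_frac2d = phi2d / np.pi
    phi_frac2d = np.clip(phi_frac2d, 0.0, 1.0 - 1e-9)

    labels = np.zeros(spec.grid_shape, dtype=np.int64)
    labels[:, cavity2d] = SUBCORTICAL_ID

    layout = spec.layout()
    ap_frac = (np.arange(n_ap) + 0.5) / n_ap
    shell_assigned = np.zeros(spec.grid_shape, dtype=bool)
    for idx, (phi_lo, phi_hi, ap_lo, ap_hi) in enumerate(layout):
        in_phi = (phi_frac2d >= phi_lo) & (phi_frac2d < phi_hi) & shell2d
        in_ap = (ap_frac >= ap_lo) & (ap_frac < ap_hi)
        sel = in_ap[:, None, None] & in_phi[None, :, :]
        labels[sel] = AREA_ID_BASE + idx
        shell_assigned |= sel
    missed = np.broadcast_to(shell2d, labels.shape) & ~shell_assigned
    if missed.any():
        raise ValueError("area_seed_layout does not cover the shell; every shell voxel needs a sector")

    nodes = [
        StructureNode(ROOT_ID, "brain", None),
        StructureNode(CORTEX_ID, "cortex", ROOT_ID),
        StructureNode(SUBCORTICAL_ID, "subcortical", ROOT_ID),
    ]
    for idx in range(spec.n_areas):
        nodes.append(StructureNode(AREA_ID_BASE + idx, f"area_{idx}", CORTEX_ID))
    tree = StructureTree(nodes, cortex_root_id=CORTEX_ID)
    return AnnotationVolume(labels, voxel_size_um=spec.voxel_size_um), tree


def generate_gene_volume(
    gene: GeneSpec,
    annotation: AnnotationVolume,
    tree: StructureTree,
    noise: NoiseSpec,
    rng_seed,
) -> ExpressionVolume:
    """Render one gene on the annotation lattice and apply acquisition noise.

    Order of corruption: additive Gaussian voxel noise, per-coronal-section
    multiplicative banding, zeroed missing sections, clip to [0, 1].
    """
    gene.validate()
    noise.validate()
    labels = annotation.labels
    n_ap = labels.shape[0]
    shell = cortex_mask(annotation, tree)
    tissue = (labels > 0) & ~shell

    base = np.zeros(labels.shape, dtype=np.float64)
    base[tissue] = noise.background_level
    if gene.kind == "uniform":
        base[shell] = gene.level
    elif gene.kind == "noise_only":
        base[shell] = 0.0
    elif gene.kind == "gradient":
        size = labels.shape[gene.axis]
        coord = np.arange(size, dtype=np.float64) / max(size - 1, 1)
        ramp_shape = [1, 1, 1]
        ramp_shape[gene.axis] = size
        ramp = np.broadcast_to(
            (gene.low + (gene.high - gene.low) * coord).reshape(ramp_shape), labels.shape
        )
        base[shell] = ramp[shell]
    elif gene.kind == "border_marker":
        if gene.target_area not in tree:
            raise KeyError(f"gene {gene.gene_id}: unknown target_area {gene.target_area}")
        inside = area_mask(annotation, tree, gene.target_area)
        base[shell] = gene.outside_level
        base[inside] = gene.inside_level
        if gene.inside_level_right is not None:
            midline = (labels.shape[2] - 1) / 2.0
            right = np.zeros(labels.shape, dtype=bool)
            right[:, :, np.arange(labels.shape[2]) > midline] = True
            base[inside & right] = gene.inside_level_right

    rng = np.random.default_rng(rng_seed)
    noisy_region = shell | tissue
    if gene.noise_sd > 0:
        base[noisy_region] += rng.normal(0.0, gene.noise_sd, int(noisy_region.sum()))
    lo, hi = noise.banding_factor_range
    factors = rng.uniform(lo, hi, n_ap)
    base *= factors[:, None, None]
    dropped = rng.random(n_ap) < noise.missing_band_probability
    base[dropped] = 0.0
    np.clip(base, 0.0, 1.0, out=base)
    return ExpressionVolume(gene_id=gene.gene_id, values=base, voxel_size_um=annotation.voxel_size_um)


@dataclass
class StudyData(AtlasProvider):
    """A generated study: volumes, annotation, hierarchy, and ground truth."""

    spec: SyntheticSpec
    volumes: list[ExpressionVolume]
    _annotation: AnnotationVolume
    _tree: StructureTree
    ground_truth: pd.DataFrame  # columns gene_id, kind, target_area (markers only)

    def annotation(self) -> AnnotationVolume:
        return self._annotation

    def structure_tree(self) -> StructureTree:
        return self._tree

    def gene_ids(self) -> list[str]:
        return [v.gene_id for v in self.volumes]

    def expression(self, gene_id: str) -> ExpressionVolume:
        for v in self.volumes:
            if v.gene_id == gene_id:
                return v
        raise KeyError(f"no volume for gene {gene_id}")

    def marker_map(self) -> dict[int, list[str]]:
        """area label id -> gene ids planted as its border markers."""
        out: dict[int, list[str]] = {}
        for row in self.ground_truth.itertuples():
            out.setdefault(int(row.target_area), []).append(row.gene_id)
        return out


def generate_study(spec: SyntheticSpec) -> StudyData:
    """Generate one volume per gene spec plus the shared annotation.

    Per-gene randomness is seeded as ``(spec.rng_seed, gene_index)`` so each
    volume is reproducible independently of the others.
    """
    spec.validate()
    annotation, tree = generate_annotation(spec)
    volumes = [
        generate_gene_volume(gene, annotation, tree, spec.noise, [spec.rng_seed, idx])
        for idx, gene in enumerate(spec.gene_specs)
    ]
    rows = [
        {"gene_id": g.gene_id, "kind": g.kind, "target_area": g.target_area}
        for g in spec.gene_specs
        if g.kind == "border_marker"
    ]
    truth = pd.DataFrame(rows, columns=["gene_id", "kind", "target_area"])
    return StudyData(spec=spec, volumes=volumes, _annotation=annotation, _tree=tree, ground_truth=truth)


def marker_panel(
    n_areas: int = 4,
    n_genes: int = 50,
    markers_per_area: int = 1,
    inside_level: float = 0.9,
    outside_level: float = 0.1,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> list[GeneSpec]:
    """A standard test panel: one (or more) planted marker per area, the rest
    a deterministic mixture of uniform, gradient and pure-noise genes."""
    n_marker = n_areas * markers_per_area
    if n_genes < n_marker:
        raise ValueError("n_genes smaller than the number of planted markers")
    rng = np.random.default_rng([seed, 987])
    genes: list[GeneSpec] = []
    for a in range(n_areas):
        for m in range(markers_per_area):
            genes.append(
                GeneSpec.border_marker(
                    f"marker_a{a}_{m}", AREA_ID_BASE + a, inside_level, outside_level, noise_sd=noise_sd
                )
            )
    fillers = n_genes - n_marker
    for i in range(fillers):
        mod = i % 3
        if mod == 0:
            genes.append(GeneSpec.uniform(f"uniform_{i}", float(rng.uniform(0.1, 0.9)), noise_sd=noise_sd))
        elif mod == 1:
            lo, hi = sorted(rng.uniform(0.0, 1.0, 2))
            genes.append(GeneSpec.gradient(f"gradient_{i}", int(rng.integers(0, 3)), float(lo), float(hi), noise_sd=noise_sd))
        else:
            genes.append(GeneSpec.noise_only(f"noise_{i}", noise_sd=max(noise_sd, 0.02)))
    return genes
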