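import numpy as np
import pytest

from cortexscreen import atlas, projection as prj
from cortexscreen.synthetic import (
    GeneSpec,
    NoiseSpec,
    SyntheticSpec,
    generate_study,
    marker_panel,
)

# A compact study reused (read-only) across test modules.
SMALL_GRID = (40, 24, 44)
SMALL_INNER = 14.0
SMALL_THICK = 5.0


def small_spec(**overrides) -> SyntheticSpec:
    defaults = dict(
        grid_shape=SMALL_GRID,
        shell_inner_radius=SMALL_INNER,
        shell_thickness=SMALL_THICK,
        n_areas=4,
        rng_seed=3,
        gene_specs=marker_panel(n_areas=4, n_genes=12, seed=3),
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


@pytest.fixture(scope="session")
def base_spec():
    return small_spec()


@pytest.fixture(scope="session")
def base_study(base_spec):
    return generate_study(base_spec)


@pytest.fixture(scope="session")
def base_cortex_mask(base_study):
    return atlas.cortex_mask(base_study.annotation(), base_study.structure_tree())


@pytest.fixture(scope="session")
def top_mapping(base_cortex_mask):
    return prj.build_surface_mapping(base_cortex_mask, "top")


@pytest.fixture(scope="session")
def flat_mapping(base_cortex_mask):
    return prj.build_surface_mapping(base_cortex_mask, "flatmap")


@pytest.fixture(scope="session")
def top_projections(base_study, top_mapping):
    return [prj.project_volume(v, top_mapping) for v in base_study.volumes]


@pytest.fixture(scope="session")
def top_area_masks(base_study, top_mapping, base_spec):
    ann, tree = base_study.annotation(), base_study.structure_tree()
    return {
        aid: prj.project_area_mask(atlas.area_mask(ann, tree, aid), top_mapping, aid)
        for aid in base_spec.area_ids()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
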