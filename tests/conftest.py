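import numpy as np
import pytest

from dnadamage.geometry import (Domain, NucleusModel, PlacedVoxel,
                                TerritorySpec, build_nucleus, build_voxel)


@pytest.fixture(scope="session")
def straight_voxel():
    return build_voxel("straight")


@pytest.fixture(scope="session")
def turn_voxel():
    return build_voxel("up")


@pytest.fixture(scope="session")
def desk_model():
    """One-chromosome, one-domain genome small enough for exhaustive checks."""
    return build_nucleus([TerritorySpec("1", 1)], 7,
                         half_axes_nm=(700.0, 600.0, 500.0),
                         domain_radius_nm=120.0)


@pytest.fixture(scope="session")
def desk_index(desk_model):
    return desk_model.build_index()


@pytest.fixture(scope="session")
def single_voxel_model():
    """A nucleus holding exactly one straight voxel at the origin."""
    rng = np.random.default_rng(123)
    voxel = build_voxel("straight")
    dom = Domain(domain_id=0, chromosome_id="1",
                 center=np.zeros(3), radius=60.0,
                 placements=[PlacedVoxel(
                     kind="straight", center=np.zeros(3),
                     rotation=np.eye(3, dtype=int), bp_start=0,
                     n_bp=voxel.n_bp)],
                 sequence=rng.integers(0, 4, voxel.n_bp).astype(np.uint8))
    model = NucleusModel((200.0, 200.0, 200.0),
                         [TerritorySpec("1", 1, voxel.n_bp)], [dom])
    return model


@pytest.fixture(scope="session")
def single_voxel_index(single_voxel_model):
    return single_voxel_model.build_index()
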