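import numpy as np
import pytest

from tcmdose import phantoms, source, tcm


@pytest.fixture(scope="session")
def female_ct():
    return phantoms.generate_thorax_phantom(
        "female", 24.0, breast_lateral_offset=0.0, n_slices=16, seed=7, grid_size=96
    )


@pytest.fixture(scope="session")
def female_phantom(female_ct):
    return phantoms.build_voxel_model(female_ct)


@pytest.fixture(scope="session")
def force_source():
    return source.calibrate_to_hvl(8.0, 120)


@pytest.fixture()
def flat_scheme():
    theta = np.arange(36) * 2.0 * np.pi / 36.0
    z = np.arange(10) * 1.0
    return tcm.TCMScheme(
        table_positions=z,
        angle_bins=theta,
        current=np.full((10, 36), 100.0),
        provenance="file",
    )


def water_cylinder_phantom(diameter_cm=20.0, n_slices=12, pixel_cm=0.5, dz_cm=1.0, pad_cm=2.0):
    """Homogeneous unit-density water cylinder along z, surrounded by air."""
    import tcmdose.physics as physics

    nxy = int(np.ceil((diameter_cm + 2 * pad_cm) / pixel_cm))
    c = (nxy - 1) / 2.0
    y, x = np.meshgrid(
        (np.arange(nxy) - c) * pixel_cm, (np.arange(nxy) - c) * pixel_cm, indexing="ij"
    )
    inside = x**2 + y**2 <= (diameter_cm / 2.0) ** 2
    mat = np.where(inside, physics.WATER, physics.AIR).astype(np.uint8)
    rho = np.where(inside, 1.0, physics.AIR_DENSITY if hasattr(physics, "AIR_DENSITY") else 0.0012)
    mat = np.broadcast_to(mat, (n_slices, nxy, nxy)).copy()
    rho = np.broadcast_to(rho, (n_slices, nxy, nxy)).copy()
    return phantoms.VoxelPhantom(
        material_id=mat, density=rho, voxel_size=(dz_cm, pixel_cm, pixel_cm), organ_masks={}
    )
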