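import numpy as np
import pytest

from ocdvc import DVCConfig, PhantomSpec, build_grid, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """64³ phantom with mask: enough for one strut period at 10 µm voxels."""
    spec = PhantomSpec(shape=(64, 64, 64), voxel_size_um=10.0, seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def medium_phantom():
    """96³ phantom used by correlator tests that need interior grid points."""
    spec = PhantomSpec(shape=(96, 96, 96), voxel_size_um=10.0, seed=11)
    return generate_phantom(spec)


def sharp_spec(shape=(96, 96, 96), seed=11):
    """Feature-rich, unblurred speckle: every subvolume carries unique
    pattern, so correlator identity checks are well-posed (texture-poor
    windows are a measurement limit, not a correlator property)."""
    return PhantomSpec(
        shape=shape,
        voxel_size_um=10.0,
        seed=seed,
        psf_sigma_um=0.0,
        speckle_grain_um={"bone": 30.0, "cartilage": 20.0, "new_tissue": 20.0, "void": 20.0},
    )


@pytest.fixture(scope="session")
def sharp_phantom():
    return generate_phantom(sharp_spec())


@pytest.fixture
def default_config():
    return DVCConfig()


@pytest.fixture
def uniform_field():
    """Displacement field factory: constant vector on a small grid."""
    from ocdvc import DisplacementField

    def make(vector_um, shape=(64, 64, 64), size=16, voxel=10.0):
        grid = build_grid(shape, size, 0.5, voxel)
        n = grid.n_points
        vec = np.tile(np.asarray(vector_um, dtype=float), (n, 1))
        return DisplacementField(grid, vec, np.ones(n), np.ones(n, dtype=bool))

    return make


@pytest.fixture
def analytic_field():
    """Field factory from a displacement function of physical (x, y, z) µm."""
    from ocdvc import DisplacementField

    def make(fn, shape=(64, 64, 64), size=16, voxel=10.0):
        grid = build_grid(shape, size, 0.5, voxel)
        vec = np.asarray(fn(grid.positions_um()), dtype=float)
        n = grid.n_points
        return DisplacementField(grid, vec, np.ones(n), np.ones(n, dtype=bool))

    return make
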