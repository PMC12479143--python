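import numpy as np
import pytest

from hypersar import (
    ApplicatorGeometry,
    DesignGrid,
    LayerSpec,
    build_head_phantom,
    generate_dataset,
    load_tissue_registry,
)


@pytest.fixture(scope="session")
def geometry():
    return ApplicatorGeometry()


@pytest.fixture(scope="session")
def registry():
    return load_tissue_registry()


@pytest.fixture(scope="session")
def phantom():
    """Small layered phantom shared by the suite (deterministic)."""
    return build_head_phantom(400, seed=7)


@pytest.fixture(scope="session")
def homogeneous_phantom():
    """All-brain sphere used for steering-fidelity properties."""
    return build_head_phantom(
        5000,
        seed=7,
        layer_spec=LayerSpec(brain_radii=(9.0, 9.0, 9.0), thicknesses={}, air_pocket_radius=0.0),
    )


@pytest.fixture(scope="session")
def records(phantom, geometry):
    """A handful of surrogate samples on the shared phantom."""
    grid = DesignGrid(z_values=(0.0,))
    return generate_dataset(grid, phantom, geometry, 8, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
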