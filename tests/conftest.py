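import numpy as np
import pytest

from transoval import phantom, trajectory


@pytest.fixture(scope="session")
def canonical_scene():
    """The default right-side phantom at full mesh resolution."""
    return phantom.generate_phantom(phantom.canonical_config())


@pytest.fixture(scope="session")
def canonical_aperture(canonical_scene):
    return trajectory.build_aperture(canonical_scene)


@pytest.fixture(scope="session")
def canonical_context(canonical_scene, canonical_aperture):
    return trajectory.TrajectoryContext(canonical_scene, canonical_aperture)


@pytest.fixture(scope="session")
def coarse_scene():
    """Coarser-mesh phantom for tests where resolution is not the point."""
    return phantom.generate_phantom(phantom.canonical_config(mesh_voxel_mm=0.7))


@pytest.fixture(scope="session")
def coarse_aperture(coarse_scene):
    return trajectory.build_aperture(coarse_scene)


@pytest.fixture(scope="session")
def coarse_context(coarse_scene, coarse_aperture):
    return trajectory.TrajectoryContext(coarse_scene, coarse_aperture)


@pytest.fixture(scope="session")
def closedform_scene():
    import closedform

    return phantom.generate_phantom(closedform.build_config())


@pytest.fixture(scope="session")
def closedform_aperture(closedform_scene):
    return trajectory.build_aperture(closedform_scene)


@pytest.fixture(scope="session")
def closedform_context(closedform_scene, closedform_aperture):
    return trajectory.TrajectoryContext(closedform_scene, closedform_aperture)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
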