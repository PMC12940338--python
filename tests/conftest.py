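import numpy as np
import pytest
import trimesh

from paleomorph.synthetic import (
    ShellToothSpec,
    balanced_vbi_spec,
    make_shell_tooth,
)


@pytest.fixture(scope="session")
def unit_sphere_mesh() -> trimesh.Trimesh:
    return trimesh.creation.icosphere(subdivisions=2, radius=1.0)


@pytest.fixture(scope="session")
def spherical_shell_mesh() -> tuple[trimesh.Trimesh, int]:
    """Solid spherical shell (outer r=1, wall 0.5) and its outer-vertex count."""
    outer = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    inner = trimesh.creation.icosphere(subdivisions=2, radius=0.5)
    inner.invert()
    shell = trimesh.util.concatenate([outer, inner])
    assert shell.is_watertight
    return shell, len(outer.vertices)


@pytest.fixture(scope="session")
def shell_tooth_fine():
    """Shell-model tooth at 33 voxels across the dentine radius."""
    spec = ShellToothSpec(voxel=0.15)
    return make_shell_tooth(spec)


@pytest.fixture(scope="session")
def balanced_tooth():
    """Phantom constructed so cervix pulp volume equals branch canal volume."""
    return make_shell_tooth(balanced_vbi_spec())


@pytest.fixture(scope="session")
def dimple_tooth():
    """Shell tooth with a spherical-cap occlusal basin of known depth."""
    spec = ShellToothSpec(voxel=0.2, basin_dimple_depth=0.6, basin_dimple_radius=1.5)
    return make_shell_tooth(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
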