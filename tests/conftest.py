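import numpy as np
import pytest
import trimesh

from kneemorph.mesh_core import CorrespondedMesh


def icosphere(subdiv: int = 3, radius: float = 10.0,
              label: str = "other") -> CorrespondedMesh:
    m = trimesh.creation.icosphere(subdivisions=subdiv, radius=radius)
    return CorrespondedMesh(np.asarray(m.vertices), np.asarray(m.faces),
                            bone_label=label)


@pytest.fixture(scope="session")
def unit_icosphere():
    return icosphere(3, 1.0)


@pytest.fixture(scope="session")
def sphere10():
    """Radius-10 icosphere used as the standard wrap/query obstacle."""
    return icosphere(4, 10.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny noise-free cohort shared by cartilage/validation tests."""
    from kneemorph.synthetic import SyntheticCohortSpec, generate_cohort

    return generate_cohort(SyntheticCohortSpec(
        n_cases=3, seed=11, thickness_sigma=0.0, subdivision=(3, 3, 2)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
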