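import numpy as np
import pytest

import stenoshape as ss


@pytest.fixture(scope="session")
def consts():
    return ss.FluidConstants()


@pytest.fixture(scope="session")
def small_cohort(consts):
    """A 16-geometry seeded cohort shared by the cheaper tests."""
    profiles, meshes, manifest = ss.generate_cohort(16, seed=42)
    return profiles, meshes, manifest


@pytest.fixture(scope="session")
def template(consts):
    return ss.straight_template(consts)


@pytest.fixture(scope="session")
def shape_model(small_cohort, template):
    _, meshes, _ = small_cohort
    disps = [ss.displacement_field(template, m) for m in meshes]
    return ss.fit_shape_model(disps, n_modes=5, template=template)


@pytest.fixture(scope="session")
def campaign(small_cohort, consts):
    profiles, _, manifest = small_cohort
    return ss.run_campaign(profiles, ss.OracleConfig(seed=7), consts,
                           geometry_ids=manifest["id"].tolist())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
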