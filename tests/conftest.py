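import numpy as np
import pytest

from meniscimech import (
    ExperimentPlan,
    LoadCase,
    SolverConfig,
    default_ligaments,
    default_materials,
    make_intact_joint,
    run_suite,
    symmetric_materials,
)


@pytest.fixture(scope="session")
def ligaments():
    return default_ligaments()


@pytest.fixture(scope="session")
def materials():
    return default_materials()


@pytest.fixture(scope="session")
def intact_joint():
    return make_intact_joint()


@pytest.fixture(scope="session")
def symmetric_setup(materials):
    """Mirror-symmetric joint with side-averaged horn attachments."""
    return make_intact_joint({"symmetric": True}), symmetric_materials(materials)


@pytest.fixture(scope="session")
def full_load():
    return LoadCase(compressive_force=1000.0, n_increments=10)


@pytest.fixture(scope="session")
def suite_table():
    """The headline 9-variant x 2-mode outcome table at 1000 N (shared)."""
    return run_suite(ExperimentPlan())


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def admissible_gradient(rng, ligament, scale=0.1):
    """Random deformation gradient with det > 0, fiber stretch clear of the
    branch points of the fiber law (where finite differences are invalid)."""
    while True:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) < 0.05:
            continue
        a = rng.standard_normal(3)
        a /= np.linalg.norm(a)
        lam = float(np.linalg.norm(F @ a))
        if abs(lam - 1.0) < 5e-3 or abs(lam - ligament.lambda_star) < 5e-3:
            continue
        return F, a
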