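import numpy as np
import pytest

from laminareeg import (
    BemSolver,
    PopulationSpec,
    StimulusSpec,
    build_nested_spheres,
    place_montage,
    simulate_column_currents,
)

PAPER_CONDUCTIVITIES = (0.33, 0.0063, 0.43, 0.0)  # brain, skull, scalp, air
SPHERE_RADII = (30.0, 35.0, 38.0)


@pytest.fixture(scope="session")
def head_model():
    return build_nested_spheres(SPHERE_RADII, 3, PAPER_CONDUCTIVITIES)


@pytest.fixture(scope="session")
def bem_solver(head_model):
    """Level-3 three-shell solver shared across the suite (assembly ~10 s)."""
    return BemSolver(head_model)


@pytest.fixture(scope="session")
def montage_1010(head_model):
    return place_montage(head_model.scalp, "10-10")


@pytest.fixture(scope="session")
def small_column_currents():
    """Scaled-down column (220 L3 + 100 L5) under the standard stimulus."""
    return simulate_column_currents(
        PopulationSpec(n_l3=220, n_l5=100), StimulusSpec(mean_na=1.90), seed=1
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
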