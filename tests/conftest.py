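import pytest

from fitsort import (
    ClassProfile,
    classify_from_bounds,
    compute_value_matrix,
    huol_fixture,
    huol_reference_bounds,
)


@pytest.fixture(scope="session")
def huol():
    return huol_fixture()


@pytest.fixture(scope="session")
def huol_values(huol):
    return compute_value_matrix(huol.matrix)


@pytest.fixture(scope="session")
def ref_bounds():
    return huol_reference_bounds()


@pytest.fixture(scope="session")
def ref_classification(ref_bounds, huol):
    return classify_from_bounds(ref_bounds, huol.profile)


@pytest.fixture
def profile():
    return ClassProfile(labels=("M", "B", "W"), thresholds=(0.4, 0.7))
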