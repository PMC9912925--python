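import numpy as np
import pytest

from qmrestraints.fixtures import FixtureSpec, generate_fixture

LIGAND_SELECTOR = ("A", "LIG", 1)


@pytest.fixture(scope="session")
def clean_fixture():
    """Unperturbed pocket + ligand + dictionary."""
    return generate_fixture(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def perturbed_fixture():
    """Fixture with the rotatable torsions displaced by 40 degrees."""
    return generate_fixture(FixtureSpec(seed=11, perturbation=(0.0, 0.0, 40.0)))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
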