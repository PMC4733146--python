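import numpy as np
import pytest

import multitrait as mt


@pytest.fixture(scope="session")
def high_g0() -> mt.TraitCovariance:
    return mt.TraitCovariance(
        np.array([[1.0, 0.4, 0.6], [0.4, 1.5, 0.9], [0.6, 0.9, 2.5]]), "genetic"
    )


@pytest.fixture(scope="session")
def high_r0() -> mt.TraitCovariance:
    return mt.TraitCovariance(
        np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]]), "residual"
    )


@pytest.fixture(scope="session")
def low_g0() -> mt.TraitCovariance:
    return mt.TraitCovariance(
        np.array([[5.0, -2.0, 3.0], [-2.0, 7.0, 4.0], [3.0, 4.0, 10.0]]), "genetic"
    )


@pytest.fixture(scope="session")
def low_r0() -> mt.TraitCovariance:
    return mt.TraitCovariance(
        np.array([[20.0, -5.0, 1.0], [-5.0, 28.0, 3.0], [1.0, 3.0, 35.0]]), "residual"
    )


@pytest.fixture(scope="session")
def small_relmat() -> mt.RelationshipMatrix:
    """A, for a 3x3 factorial design: 6 founders + 9 offspring."""
    return mt.build_a_matrix(mt.make_factorial_pedigree(3, 3))


@pytest.fixture(scope="session")
def small_data(small_relmat, high_g0, high_r0):
    """One simulated replicate on the small design (15 individuals)."""
    phenotypes, truth = mt.simulate_traits(small_relmat, high_g0, high_r0, seed=42)
    return mt.MultiTraitData(phenotypes, small_relmat), truth


def random_pd_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """A well-conditioned random symmetric positive-definite matrix."""
    B = rng.standard_normal((n, n))
    return B @ B.T + n * np.eye(n)
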