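import numpy as np
import pytest

from culturopt.model import Condition, IncidenceMatrix
from culturopt.simulate import study_shaped_fixture


@pytest.fixture
def toy_matrix():
    """5 species × 3 conditions with a hand-tallied fill.

    Column richness: c1=3, c2=2, c3=2; s4 only in c3, s2/s5 only in c1.
    """
    cells = [
        [1, 1, 0],  # s1
        [1, 0, 0],  # s2
        [0, 1, 1],  # s3
        [0, 0, 1],  # s4
        [1, 0, 0],  # s5
    ]
    return IncidenceMatrix(cells, ["s1", "s2", "s3", "s4", "s5"], ["c1", "c2", "c3"])


@pytest.fixture
def grouped_matrix():
    """8 species × 4 conditions with two tagged groups and atmospheres."""
    cells = [
        [1, 0, 0, 0],
        [1, 1, 0, 0],
        [0, 1, 1, 0],
        [0, 0, 1, 1],
        [0, 0, 0, 1],
        [1, 0, 0, 1],
        [0, 1, 0, 0],
        [1, 1, 1, 1],
    ]
    meta = {
        "g1a": Condition(id="g1a", atmosphere="anaerobic", group="g1"),
        "g1b": Condition(id="g1b", atmosphere="anaerobic", group="g1"),
        "g2a": Condition(id="g2a", atmosphere="aerobic", group="g2"),
        "g2b": Condition(id="g2b", atmosphere="aerobic", group="g2"),
    }
    return IncidenceMatrix(
        cells,
        [f"sp{i}" for i in range(1, 9)],
        ["g1a", "g1b", "g2a", "g2b"],
        condition_meta=meta,
    )


@pytest.fixture(scope="session")
def study_fixture():
    """One study-shaped synthetic dataset shared across tests."""
    return study_shaped_fixture(seed=7)


def random_matrix(rng: np.random.Generator, n_species: int, n_conditions: int):
    """Random dense-enough incidence matrix honouring the no-empty-row rule."""
    cells = rng.random((n_species, n_conditions)) < rng.uniform(0.15, 0.5)
    empty = ~cells.any(axis=1)
    cells[empty, rng.integers(0, n_conditions, int(empty.sum()))] = True
    return IncidenceMatrix(
        cells,
        [f"sp{i:03d}" for i in range(n_species)],
        [f"c{j:02d}" for j in range(n_conditions)],
    )
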