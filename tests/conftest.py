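import numpy as np
import pandas as pd
import pytest

from enterostrat import CountTable, TaxonomyMap, simulate_yule_tree


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_counts():
    """5 samples x 4 taxa with known structure."""
    data = pd.DataFrame(
        [
            [5, 5, 5, 5],
            [1, 1, 2, 0],
            [10, 0, 0, 0],
            [2, 2, 0, 0],
            [0, 3, 3, 0],
        ],
        index=[f"s{i}" for i in range(1, 6)],
        columns=[f"t{i}" for i in range(1, 5)],
    )
    return CountTable(data)


@pytest.fixture
def toy_taxonomy():
    lineages = {
        "t1": ("Bacteria", "P1", "C1", "O1", "F1", "GenA", ""),
        "t2": ("Bacteria", "P1", "C1", "O1", "F1", "GenA", ""),
        "t3": ("Bacteria", "P2", "C2", "O2", "F2", "GenB", ""),
        "t4": ("Bacteria", "P2", "C2", "O2", "F2", "", ""),  # unassigned genus
    }
    return TaxonomyMap(lineages)


@pytest.fixture(scope="session")
def small_tree():
    return simulate_yule_tree(20, seed=1, ultrametric=True)


def random_composition(rng, n):
    w = rng.lognormal(0, 1, n)
    return w / w.sum()


@pytest.fixture
def multinomial_table():
    """30 samples x 60 taxa drawn iid from one composition (no structure)."""
    rng = np.random.default_rng(7)
    p = random_composition(rng, 60)
    counts = np.vstack([rng.multinomial(2000, p) for _ in range(30)])
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(30)],
            columns=[f"t{j}" for j in range(60)],
        )
    )
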