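import numpy as np
import pandas as pd
import pytest

from hetvar.pedigree import Pedigree


def random_pedigree(n_founders: int, n_total: int, seed: int) -> Pedigree:
    """Random overlapping-generation pedigree with possible inbreeding."""
    rng = np.random.default_rng(seed)
    sire = np.full(n_total, -1, dtype=np.int64)
    dam = np.full(n_total, -1, dtype=np.int64)
    for i in range(n_founders, n_total):
        s, d = rng.choice(i, size=2, replace=False)
        sire[i], dam[i] = s, d
    return Pedigree(ids=pd.Index([f"A{i}" for i in range(n_total)]), sire=sire, dam=dam)


@pytest.fixture
def trio() -> Pedigree:
    frame = pd.DataFrame(
        {"animal": ["S", "D", "C"], "sire": [None, None, "S"], "dam": [None, None, "D"]}
    )
    return Pedigree.from_frame(frame)


@pytest.fixture
def fullsib_mating() -> Pedigree:
    """Offspring of two full sibs: F = 0.25."""
    frame = pd.DataFrame(
        {
            "animal": ["P1", "P2", "B", "C", "X"],
            "sire": [None, None, "P1", "P1", "B"],
            "dam": [None, None, "P2", "P2", "C"],
        }
    )
    return Pedigree.from_frame(frame)


@pytest.fixture(scope="session")
def fa_small():
    from hetvar.simulate import make_benchmark_dataset

    return make_benchmark_dataset("fa_m3", n_animals=800, seed=42)


@pytest.fixture(scope="session")
def homo_small():
    from hetvar.simulate import make_benchmark_dataset

    return make_benchmark_dataset("homoscedastic", n_animals=800, seed=43)
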