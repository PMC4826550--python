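import numpy as np
import pandas as pd
import pytest

from famvar.pedigree import Pedigree
from famvar.simulate import SimulationConfig, simulate_dataset


def make_pedigree(rows):
    """rows: (family, individual, father, mother, sex)."""
    return Pedigree(
        pd.DataFrame(rows, columns=["family", "individual", "father", "mother", "sex"])
    )


@pytest.fixture
def nuclear_family():
    return make_pedigree(
        [
            ("F1", "dad", None, None, "male"),
            ("F1", "mom", None, None, "female"),
            ("F1", "kid1", "dad", "mom", "male"),
            ("F1", "kid2", "dad", "mom", "female"),
        ]
    )


@pytest.fixture
def three_generations():
    """Founder grandparents, two sib parents with married-in spouses, cousins."""
    return make_pedigree(
        [
            ("F1", "gp", None, None, "male"),
            ("F1", "gm", None, None, "female"),
            ("F1", "p1", "gp", "gm", "male"),
            ("F1", "p2", "gp", "gm", "female"),
            ("F1", "s1", None, None, "female"),
            ("F1", "s2", None, None, "male"),
            ("F1", "c1", "p1", "s1", "male"),
            ("F1", "c2", "s2", "p2", "female"),
        ]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Clean synthetic dataset shared across read-only tests."""
    cfg = SimulationConfig(seed=11, n_families=25, n_genes=10)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def degraded_dataset():
    cfg = SimulationConfig(
        seed=13,
        n_families=25,
        n_genes=10,
        mendel_error_rate=0.001,
        missingness_rate=0.05,
        low_coverage_fraction=0.1,
        low_quality_fraction=0.1,
        capture_gap_fraction=0.05,
    )
    return simulate_dataset(cfg)
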