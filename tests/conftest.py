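import numpy as np
import pandas as pd
import pytest

from poenet.simulate import GroundTruth, make_design, simulate_allelic_counts


@pytest.fixture(scope="session")
def f1_design():
    """The sequenced reciprocal-cross cohort: 4 animals per cross/sex/diet cell."""
    return make_design(4, "F1")


@pytest.fixture(scope="session")
def full_design():
    """The full experimental cohort: 12 animals per cell, 96 in total."""
    return make_design(12, "F1")


@pytest.fixture(scope="session")
def imprinted_truth():
    """One paternally and one maternally expressed gene among 40 biallelic ones."""
    return GroundTruth(
        ase_genes={
            "g0000": {"LxS": 0.02, "SxL": 0.98},  # paternal L expression in SxL
            "g0001": {"LxS": 0.95, "SxL": 0.05},  # maternal
        }
    )


@pytest.fixture(scope="session")
def gene_ids():
    return [f"g{i:04d}" for i in range(40)]


@pytest.fixture(scope="session")
def allelic_counts(f1_design, imprinted_truth, gene_ids):
    return simulate_allelic_counts(
        f1_design, imprinted_truth, gene_ids, depth_mean=100, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def toy_counts():
    """Deterministic 6-gene x 4-sample count matrix for normalization tests."""
    data = np.array(
        [
            [100, 200, 100, 400],
            [50, 100, 50, 200],
            [10, 20, 10, 40],
            [500, 1000, 500, 2000],
            [80, 160, 80, 320],
            [30, 60, 30, 120],
        ],
        dtype=float,
    )
    return pd.DataFrame(data, index=[f"g{i}" for i in range(6)],
                        columns=[f"s{i}" for i in range(4)])
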