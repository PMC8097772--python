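import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from netbim.data_io import Flavour, PairDataset
from netbim.simulate import SimConfig, simulate_binding_dataset, simulate_immunogenic_dataset


@pytest.fixture(scope="session")
def small_binding_ds():
    ds, truth = simulate_binding_dataset(
        SimConfig(n_alleles=12, peptides_per_allele=12, seed=11)
    )
    return ds, truth


@pytest.fixture(scope="session")
def small_immunogenic_ds():
    ds, truth = simulate_immunogenic_dataset(
        SimConfig(n_alleles=12, peptides_per_allele=12, seed=12)
    )
    return ds, truth


@pytest.fixture
def star_dataset():
    """One allele measured against three peptides at IC50 1, 500, 50000 nM."""
    df = pd.DataFrame(
        {
            "allele": ["HLA-A*02:01"] * 3,
            "peptide": ["AAAAAAAAA", "CCCCCCCCC", "DDDDDDDDD"],
            "ic50_nm": [1.0, 500.0, 50000.0],
        }
    )
    return PairDataset(df=df, flavour=Flavour.BINDING)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
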