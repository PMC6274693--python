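import pandas as pd
import pytest

from mixtox import chem_descriptors, dataset_io


@pytest.fixture(scope="session")
def compounds() -> pd.DataFrame:
    return dataset_io.load_compound_table()


@pytest.fixture(scope="session")
def mixtures(compounds) -> pd.DataFrame:
    return dataset_io.load_mixture_table(compounds=compounds)


@pytest.fixture(scope="session")
def descriptor_table(compounds) -> pd.DataFrame:
    # computed once: 55 SMILES parses + charge schemes
    return chem_descriptors.compute_descriptor_table(compounds)
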