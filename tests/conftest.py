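import numpy as np
import pandas as pd
import pytest

from phytomedia import datasets
from phytomedia.stoichiometry import ION_NAMES


@pytest.fixture(scope="session")
def treatments() -> pd.DataFrame:
    return datasets.load_treatments()


@pytest.fixture(scope="session")
def printed_ions(treatments) -> pd.DataFrame:
    return treatments[list(ION_NAMES)]


@pytest.fixture(scope="session")
def ion_matrix() -> pd.DataFrame:
    """Full-precision 34 x 18 ion matrix recomputed from the design."""
    X = datasets.load_ion_matrix(printed=False)
    X.columns = list(ION_NAMES)
    return X


@pytest.fixture(scope="session")
def response_means() -> pd.DataFrame:
    return datasets.load_response_means()


@pytest.fixture(scope="session")
def ms():
    return datasets.ms_recipe()


@pytest.fixture(scope="session")
def ion_models():
    """Neurofuzzy models of all six responses (fitted once per session)."""
    from phytomedia.pipeline import fit_ion_models

    return fit_ion_models()


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)


@pytest.fixture(scope="session")
def print_tolerance() -> np.ndarray:
    """Tolerance for comparing recomputed ion values with printed ones:
    one unit in the last printed digit plus the error propagated from the
    design's factor levels being printed to two decimals."""
    from phytomedia.stoichiometry import FACTOR_GROUPS, salt_to_millimolar

    ms = datasets.ms_recipe()
    tol = []
    for ion in ION_NAMES:
        d = datasets.ION_PRINT_DECIMALS[ion]
        sens = sum(
            0.005 * sum(salt_to_millimolar(s, ms.concentrations[s]).get(ion, 0.0)
                        for s in salts)
            for salts in FACTOR_GROUPS.values())
        tol.append(10.0 ** (-d) + sens)
    return np.asarray(tol)
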