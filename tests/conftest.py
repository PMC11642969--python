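import numpy as np
import pandas as pd
import pytest

from paleosize import summarize_species
from paleosize.datasets import synthetic_ppwa_table


@pytest.fixture(scope="session")
def ppwa_records() -> pd.DataFrame:
    """The synthetic PPWA-shaped specimen table (fixed fixture seed)."""
    return synthetic_ppwa_table(seed=0)


@pytest.fixture(scope="session")
def ppwa_summaries(ppwa_records) -> pd.DataFrame:
    return summarize_species(ppwa_records)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
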