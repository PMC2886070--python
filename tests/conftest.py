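import numpy as np
import pandas as pd
import pytest

from crossomics.proteome import SpectralCountTable


@pytest.fixture
def small_spectral_table() -> SpectralCountTable:
    """Two species x three replicates, five proteins with varied evidence."""
    counts = pd.DataFrame(
        {
            "A_r1": [5, 2, 0, 3, 1],
            "A_r2": [0, 3, 1, 4, 2],
            "A_r3": [7, 4, 2, 5, 3],
            "B_r1": [2, 0, 3, 6, 1],
            "B_r2": [3, 0, 4, 7, 2],
            "B_r3": [4, 0, 5, 8, 3],
        },
        index=["p1", "p2", "p3", "p4", "p5"],
    )
    mw = pd.Series([50.0, 30.0, 20.0, 40.0, 10.0], index=counts.index)
    pep = pd.Series([3, 2, 2, 4, 1], index=counts.index)
    species = pd.Series({c: c.split("_")[0] for c in counts.columns})
    return SpectralCountTable(counts, mw, pep, species)


@pytest.fixture
def isoform_table() -> SpectralCountTable:
    """Three isoforms of one locus plus a singleton, two replicates."""
    counts = pd.DataFrame(
        {"A_r1": [1, 2, 3, 9], "A_r2": [0, 0, 4, 9]},
        index=["At1g10000.1", "At1g10000.2", "At1g10000.3", "At2g20000.1"],
    )
    mw = pd.Series([10.0, 20.0, 30.0, 40.0], index=counts.index)
    pep = pd.Series([2, 3, 4, 5], index=counts.index)
    species = pd.Series({"A_r1": "A", "A_r2": "A"})
    return SpectralCountTable(counts, mw, pep, species)
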