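import numpy as np
import pandas as pd
import pytest

from forestdiv import CensusTable, PlotWindow
from forestdiv.synthetic import SyntheticDesign, generate_census


def make_census(rows, window=None):
    """Build a CensusTable from (species, genus, family, x, y, dbh) tuples."""
    df = pd.DataFrame(rows, columns=["species", "genus", "family", "x", "y", "dbh"])
    df.insert(0, "tag", [f"T{i:04d}" for i in range(len(df))])
    return CensusTable(df, window or PlotWindow())


@pytest.fixture
def toy_census():
    """3 species / 2 families, hand-placed for hand-checkable tables.

    A: 5 stems dbh 10 in 5 distinct subplots; B: 3 stems dbh 20 in 2
    subplots; C: 2 stems dbh 5 in 1 subplot.
    """
    rows = [
        ("A", "Ga", "F1", 5, 5, 10), ("A", "Ga", "F1", 15, 5, 10),
        ("A", "Ga", "F1", 25, 5, 10), ("A", "Ga", "F1", 35, 5, 10),
        ("A", "Ga", "F1", 45, 5, 10),
        ("B", "Gb", "F1", 5, 15, 20), ("B", "Gb", "F1", 15, 15, 20),
        ("B", "Gb", "F1", 6, 15, 20),
        ("C", "Gc", "F2", 5, 25, 5), ("C", "Gc", "F2", 6, 25, 5),
    ]
    return make_census(rows)


@pytest.fixture(scope="session")
def synthetic_census():
    """Medium synthetic plot shared by read-only tests (fixed seed)."""
    design = SyntheticDesign(n_species=60, seed=2024)
    census, env, truth = generate_census(design)
    return census, env, truth
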