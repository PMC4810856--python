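import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from paleodiv.bins import Bin, BinScheme, tenmyr_bins
from paleodiv.occdata import COLUMNS, OccurrenceTable

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tenmyr():
    return tenmyr_bins()


@pytest.fixture
def two_bins():
    """A minimal 2-bin scheme [155,145) + [145,135)."""
    return BinScheme("toy2", (Bin("older", 155.0, 145.0), Bin("younger", 145.0, 135.0)))


@pytest.fixture
def four_bins():
    return BinScheme(
        "toy4",
        (
            Bin("b1", 160.0, 150.0),
            Bin("b2", 150.0, 140.0),
            Bin("b3", 140.0, 130.0),
            Bin("b4", 130.0, 120.0),
        ),
    )


def make_table(rows):
    """Build an OccurrenceTable from compact row tuples.

    Row: (taxon, collection, publication, age_max, age_min[, realm[, continent]]).
    """
    full = []
    for i, row in enumerate(rows):
        taxon, coll, pub, amax, amin = row[:5]
        realm = row[5] if len(row) > 5 else "nonmarine"
        continent = row[6] if len(row) > 6 else "Other"
        full.append(
            (f"o{i}", taxon, taxon.split()[0], "", coll, pub,
             float(amax), float(amin), realm, continent)
        )
    return OccurrenceTable(pd.DataFrame(full, columns=COLUMNS))


@pytest.fixture
def make_occurrences():
    return make_table
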