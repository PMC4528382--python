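import numpy as np
import pandas as pd
import pytest

from morphscape.io import MORPH_ORDER, GenotypePanel, MorphCountTable


@pytest.fixture
def tiny_panel() -> GenotypePanel:
    """Two populations x four individuals x two loci, hand-built."""
    genos = np.array(
        [
            # popA
            [[101, 101], [103, 105]],
            [[101, 103], [103, 103]],
            [[103, 103], [105, 105]],
            [[101, 101], [103, 105]],
            # popB
            [[103, 103], [105, 105]],
            [[103, 105], [105, 105]],
            [[105, 105], [103, 105]],
            [[103, 103], [105, 105]],
        ]
    )
    ids = tuple(f"popA_{i}" for i in range(1, 5)) + tuple(f"popB_{i}" for i in range(1, 5))
    pops = ("popA",) * 4 + ("popB",) * 4
    return GenotypePanel(ids, pops, ("loc1", "loc2"), genos)


@pytest.fixture
def field_counts() -> MorphCountTable:
    """Eight populations with the field study's phenotyped sample sizes.

    Counts are synthetic but keep each population's total at the reported
    N (22, 48, 29, 22, 26, 20, 21, 20; grand total 208) with all four
    morphs present.
    """
    rows = [
        ("Aroona", 5, 6, 7, 4),
        ("Wilpena", 10, 14, 16, 8),
        ("Yourambulla", 7, 8, 9, 5),
        ("WarrenGorge", 5, 8, 6, 3),
        ("DevilsPeak", 6, 7, 9, 4),
        ("Bimbowrie", 9, 4, 4, 3),
        ("MtRemarkable", 4, 5, 8, 4),
        ("TelowieGorge", 2, 4, 9, 5),
    ]
    df = pd.DataFrame(rows, columns=["population", *MORPH_ORDER])
    return MorphCountTable(df)
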