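import numpy as np
import pandas as pd
import pytest

from cecanova.io_formats import CountTable, TaxonomyMap, design_fixture


@pytest.fixture(scope="session")
def full_design() -> pd.DataFrame:
    return design_fixture()


@pytest.fixture
def toy_table() -> CountTable:
    """5 OTUs x 3 samples with mixed zero/nonzero structure."""
    counts = np.array([
        [10, 0, 4],
        [0, 7, 1],
        [3, 2, 0],
        [25, 14, 9],
        [1, 1, 1],
    ])
    return CountTable([f"OTU{i}" for i in range(1, 6)], ["S1", "S2", "S3"], counts)


@pytest.fixture
def toy_taxonomy() -> TaxonomyMap:
    lin = {
        "OTU1": "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Ruminococcaceae; g__Ruminococcus; s__",
        "OTU2": "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Lachnospiraceae; g__Blautia; s__",
        "OTU3": "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__Bacteroidaceae; g__Bacteroides; s__",
        "OTU4": "k__Bacteria; p__Firmicutes; c__Clostridia; o__; f__; g__; s__",
        "OTU5": "k__Bacteria; p__Verrucomicrobia; c__Verrucomicrobiae; o__Verrucomicrobiales; f__Verrucomicrobiaceae; g__Akkermansia; s__",
    }
    return TaxonomyMap.from_lineage_strings(lin)


@pytest.fixture
def two_cell_meta() -> pd.DataFrame:
    """Minimal two-cell design: farm A vs farm B, two samples each."""
    rows = [("S1", "A", 1, "with", "AL"), ("S2", "A", 1, "with", "AL"),
            ("S3", "B", 5, "with", "AL"), ("S4", "B", 5, "with", "AL")]
    return pd.DataFrame(rows, columns=["sample_id", "farm", "batch",
                                       "antibiotic", "feeding"])
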