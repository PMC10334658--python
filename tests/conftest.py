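import numpy as np
import pandas as pd
import pytest

from microrewire.feature_table import (FeatureTable, attach_metadata,
                                       parse_lineage)


@pytest.fixture
def toy_counts():
    """3 taxa x 4 samples counts table with case/control metadata."""
    data = pd.DataFrame(
        [[2, 0, 5, 1],
         [3, 4, 0, 1],
         [5, 6, 5, 8]],
        index=["TaxA", "TaxB", "TaxC"],
        columns=["S1", "S2", "S3", "S4"],
    )
    meta = pd.DataFrame({
        "sample_id": ["S1", "S2", "S3", "S4"],
        "dataset": ["D1", "D1", "D2", "D2"],
        "group": ["case", "case", "control", "control"],
    })
    return attach_metadata(FeatureTable(data, mode="counts"), meta)


@pytest.fixture
def lineage_counts():
    """Counts table whose taxon labels carry Greengenes-style lineages."""
    labels = [
        "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;"
        "f__Lactobacillaceae;g__Lactobacillus",
        "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;"
        "f__Streptococcaceae;g__Streptococcus",
        "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;"
        "f__Lactobacillaceae;g__Lactobacillus",
        "k__Bacteria;p__Proteobacteria;c__;o__;f__;g__",
    ]
    data = pd.DataFrame(
        [[2, 1], [4, 3], [3, 2], [1, 4]],
        index=labels, columns=["S1", "S2"],
    )
    # duplicate labels are invalid; disambiguate rows 0 and 2
    data.index = [labels[0], labels[1], labels[2] + ";s__x", labels[3]]
    meta = pd.DataFrame({
        "sample_id": ["S1", "S2"],
        "dataset": ["D1", "D1"],
        "group": ["case", "control"],
    })
    lineages = {t: parse_lineage(t) for t in data.index}
    return attach_metadata(
        FeatureTable(data, mode="counts", lineages=lineages), meta)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
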