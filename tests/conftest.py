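import numpy as np
import pytest

from inocunet.data_model import (
    Lineage,
    OtuTable,
    SampleInfo,
    SampleMetadata,
    TaxonomyTable,
    to_relative_abundance,
)


@pytest.fixture
def small_table() -> OtuTable:
    counts = np.array([
        [10, 30, 60, 0],
        [20, 20, 50, 10],
        [5, 45, 40, 10],
    ])
    return OtuTable(("s1", "s2", "s3"), ("OTU1", "OTU2", "OTU3", "OTU4"), counts)


@pytest.fixture
def small_taxonomy() -> TaxonomyTable:
    return TaxonomyTable({
        "OTU1": Lineage(kingdom="Bacteria", phylum="Actinobacteria", genus="Frankia"),
        "OTU2": Lineage(kingdom="Bacteria", phylum="Proteobacteria", genus="Dyella"),
        "OTU3": Lineage(kingdom="Bacteria", phylum="Actinobacteria",
                        genus="Nocardioides"),
        "OTU4": Lineage(kingdom="Bacteria", phylum="Chloroflexi"),
    })


@pytest.fixture
def paired_metadata() -> SampleMetadata:
    samples = {}
    for treatment in ("S6-1", "UW4", "NC", "CK"):
        for compartment, tag in (("bulk", "B"), ("rhizosphere", "R")):
            for rep in (1, 2, 3):
                samples[f"{treatment}-{tag}{rep}"] = SampleInfo(
                    treatment, compartment, rep)
    return SampleMetadata(samples)


@pytest.fixture
def small_relabund(small_table):
    return to_relative_abundance(small_table)
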