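import numpy as np
import pandas as pd
import pytest

from muskin import (
    DNA,
    RNA,
    FeatureTable,
    SampleMetadata,
    StudyBundle,
    TaxonomyTable,
    simulate_bundle,
)


@pytest.fixture(scope="session")
def default_bundle():
    """One desk-scale synthetic bundle shared by read-only tests."""
    bundle, truth = simulate_bundle(seed=11)
    return bundle, truth


@pytest.fixture(scope="session")
def decontaminated(default_bundle):
    from muskin import decontam

    bundle, truth = default_bundle
    dna, rna, report = decontam.screen_and_filter(
        bundle.table_dna, bundle.table_rna, bundle.metadata)
    return dna, rna, report, truth


@pytest.fixture
def toy_bundle():
    """Tiny hand-built valid bundle (2 features x 3 samples + 1 control)."""
    table = FeatureTable(
        ["f1", "f2"], ["s1", "s2", "s3", "c1"],
        np.array([[5, 3, 2, 1], [1, 0, 4, 0]]), DNA)
    meta = SampleMetadata(pd.DataFrame(
        {
            "group": ["g1", "g1", "g2", "control"],
            "sex": ["F", "M", "F", None],
            "concentration_dna": [2.0, 1.0, 4.0, 0.02],
            "is_negative_control": [False, False, False, True],
        },
        index=pd.Index(["s1", "s2", "s3", "c1"], name="sample_id")))
    taxonomy = TaxonomyTable(pd.DataFrame(
        {"phylum": ["P1", "P1"], "genus": ["ga", "gb"]},
        index=pd.Index(["f1", "f2"], name="feature_id")))
    return StudyBundle(table_dna=table, metadata=meta, taxonomy=taxonomy)
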