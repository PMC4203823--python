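import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bgctype.ingest import (
    FeatureTable,
    FusedDataset,
    filter_singleton_otus,
    fuse_tables,
    to_relative_abundance,
)
from bgctype.association import correlation_matrix, filter_otus_by_max_abs_correlation
from bgctype.synth import generate_dataset, paper_shape_preset

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def counts_table(values, block="16S", features=None, samples=None, taxonomy=None):
    values = np.asarray(values)
    features = features or [f"OTU_{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return FeatureTable(
        pd.DataFrame(values, index=features, columns=samples), block, "counts", taxonomy
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Generator defaults (4 planted types, 14 sampling points), seed 0."""
    return generate_dataset(paper_shape_preset(seed=0))


@pytest.fixture(scope="session")
def filtered_corr(default_dataset):
    """Fused + correlated + |rho|>=0.70-filtered matrices for the default dataset."""
    community, chemicals, truth = default_dataset
    rel = [to_relative_abundance(filter_singleton_otus(t)) for t in community.values()]
    fused = FusedDataset(
        fuse_tables(rel, "fused_community"),
        fuse_tables(list(chemicals.values()), "fused_chemicals"),
    )
    corr = correlation_matrix(fused)
    return fused, corr, filter_otus_by_max_abs_correlation(corr, 0.70), truth
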