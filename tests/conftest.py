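import numpy as np
import pytest

from mutpath import (
    MutationProfile,
    SyntheticConfig,
    VariantRecord,
    simulate_dataset,
)


def make_record(gene, sample, cohort="c1", vclass="missense", **kw):
    return VariantRecord(
        cohort_id=cohort, sample_id=sample, gene=gene, variant_class=vclass, **kw
    )


@pytest.fixture
def tiny_profile():
    """5 genes x 3 samples with a hand-chosen pattern (used by the
    exhaustive permutation oracle)."""
    X = np.array(
        [
            [1, 0, 0],
            [1, 1, 0],
            [0, 1, 0],
            [0, 0, 1],
            [0, 0, 0],
        ],
        dtype=np.int8,
    )
    genes = ["gA", "gB", "gC", "gD", "gE"]
    samples = [("c1", f"s{i}") for i in (1, 2, 3)]
    return MutationProfile(genes, samples, X)


@pytest.fixture(scope="session")
def small_dataset():
    """A scaled-down synthetic study shared across tests (read-only)."""
    config = SyntheticConfig(
        seed=11,
        n_genes=400,
        n_pathways=20,
        pathway_size_range=(5, 25),
        cohort_sizes=(40, 30),
        n_driver_pathways=2,
    )
    return simulate_dataset(config)
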