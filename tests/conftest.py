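import numpy as np
import pandas as pd
import pytest

from stableboot import CountDataset, SyntheticDesign, simulate_dataset


@pytest.fixture
def tiny_dataset() -> CountDataset:
    """3 genes x 4 samples, two paired subjects, hand-checkable numbers."""
    counts = pd.DataFrame(
        {"A_g1": [10, 0, 5], "A_g2": [20, 1, 5],
         "B_g1": [12, 0, 7], "B_g2": [18, 2, 6]},
        index=["gene1", "gene2", "gene3"])
    meta = pd.DataFrame({
        "sample_id": ["A_g1", "A_g2", "B_g1", "B_g2"],
        "subject_id": ["A", "A", "B", "B"],
        "group": ["group1", "group2", "group1", "group2"],
        "total_reads": [1_000_000, 2_000_000, 1_500_000, 1_200_000],
    })
    return CountDataset(counts, meta)


@pytest.fixture(scope="session")
def small_effect_dataset():
    """Small synthetic cohort with strong planted effects, shared read-only."""
    design = SyntheticDesign(n_subjects=8, n_genes=400, frac_de=0.05,
                             log2fc_low=2.5, log2fc_high=4.0, seed=42)
    return simulate_dataset(design)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
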