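import numpy as np
import pandas as pd
import pytest

from snrppfs import datagen, dataio


@pytest.fixture(scope="session")
def small_cohort():
    """Planted cohort small enough for per-module tests (8 MB genes, 100 noise)."""
    truth = datagen.build_truth(n_signal=8, n_noise=100, seed=1)
    cohort = datagen.sample_cohort(truth, n_tumor=60, n_normal_a=10, n_normal_b=60, seed=2)
    cohort.annotation = datagen.sample_clinical(cohort, seed=3)
    return cohort


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    return dataio.align_labels(small_cohort.expression, small_cohort.annotation)


@pytest.fixture
def toy_matrix():
    """3 genes x 6 samples with a zero-heavy gene at the filter boundary."""
    return pd.DataFrame(
        {
            "s1": [1.0, 0.0, 0.0],
            "s2": [2.0, 0.0, 0.0],
            "s3": [3.0, 0.5, 0.0],
            "s4": [4.0, 0.0, 0.0],
            "s5": [5.0, 1.0, 0.0],
            "s6": [6.0, 0.0, 1.0],
        },
        index=pd.Index(["steady", "four_zeros", "five_zeros"], name="gene_id"),
    )
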