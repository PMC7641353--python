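import numpy as np
import pandas as pd
import pytest

from mmtme import (
    SignatureMatrix,
    augment_signature,
    generate_cohort,
    generate_reference_profiles,
    minimal_cohort_params,
)
from mmtme.synthetic_data import CELL_TYPES_27


@pytest.fixture(scope="session")
def refs27():
    """Purified reference profiles for all 27 cell types (400-gene panel)."""
    return generate_reference_profiles(n_genes=400, noise_cv=0.15, seed=1)


@pytest.fixture(scope="session")
def base22(refs27):
    """A 22-type base signature built from the leukocyte marker means."""
    base_types = list(CELL_TYPES_27[:22])
    genes = [
        g
        for i, _ in enumerate(base_types)
        for g in refs27.mean_profiles.index[i * 10 : (i + 1) * 10]
    ]
    return SignatureMatrix(refs27.mean_profiles.loc[genes, base_types])


@pytest.fixture(scope="session")
def sig27(refs27, base22):
    """The augmented 27-type signature used across deconvolution tests."""
    return augment_signature(base22, refs27, list(CELL_TYPES_27[22:]), g_max=30)


@pytest.fixture(scope="session")
def cohort_minimal():
    """Small cohort with all sample types (60 patients, fast)."""
    return generate_cohort(minimal_cohort_params(), seed=3)
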