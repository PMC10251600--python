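import warnings

import numpy as np
import pytest

from liabprof.curation import CuratedCompound, CuratedDataset
from liabprof.synthetic import SARSpec, generate_library, simulate_activities

warnings.filterwarnings("ignore", message="X does not have valid feature names")


def as_dataset(df, target_id="T") -> CuratedDataset:
    return CuratedDataset(
        target_id,
        [CuratedCompound(s, float(p)) for s, p in zip(df["smiles"], df["pACTIVITY"])],
    )


@pytest.fixture(scope="session")
def library100():
    return generate_library(100, seed=17)


@pytest.fixture(scope="session")
def panel100(library100):
    """Two-target clean SAR panel of 100 compounds (mixed form, noise 0.3)."""
    clean, truth = simulate_activities(
        library100, SARSpec(noise_sd=0.3), targets=["T1", "T2"], seed=23
    )
    return clean, truth


@pytest.fixture(scope="session")
def dataset100(panel100):
    clean, _ = panel100
    return as_dataset(clean["T1"], "T1")


@pytest.fixture(scope="session")
def features100(dataset100):
    from liabprof.featurization import build_feature_matrix, similarity_matrix_from_smiles

    X, names = build_feature_matrix(dataset100)
    fps = similarity_matrix_from_smiles(dataset100.smiles)
    return X, names, fps


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20259)
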