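import numpy as np
import pytest

from radialinfo.bmp_model import SpatialDomain
from radialinfo.preprocess import preprocess_scans
from radialinfo.synthetic_data import SyntheticSpec, gen_mrna_profiles, gen_profile_ensemble


@pytest.fixture(scope="session")
def e125_ensemble():
    """Default stage-E12.5-like synthetic ensemble (default spec, seed 0)."""
    return gen_profile_ensemble(SyntheticSpec())


@pytest.fixture(scope="session")
def preprocessed(e125_ensemble):
    """Full ladder output for both signal channels plus normalization info."""
    psmad, info_p = preprocess_scans(e125_ensemble.scans, "psmad")
    sox2, info_s = preprocess_scans(e125_ensemble.scans, "sox2")
    return {"psmad": psmad, "sox2": sox2, "info_psmad": info_p, "info_sox2": info_s}


@pytest.fixture(scope="session")
def domain():
    return SpatialDomain()


@pytest.fixture(scope="session")
def mrna(domain):
    return gen_mrna_profiles(domain)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
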