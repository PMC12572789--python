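import warnings

import pytest

from mupsurv.exposure import build_mli_table, build_profiles
from mupsurv.lexicon import load_lexicon
from mupsurv.simulate import EtaTruth, GeneratorConfig, simulate_all

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def small_sim():
    """A compact synthetic study shared across pipeline tests."""
    cfg = GeneratorConfig(
        seed=11,
        n_items=40,
        n_beverage_items=6,
        n_participants=600,
        item_consumption_prob=0.2,
        truth=EtaTruth("linear", beta=0.05),
        truth_exposure_key="UPF",
    )
    return cfg, simulate_all(cfg)


@pytest.fixture(scope="session")
def small_mli(small_sim, lexicon):
    _, sim = small_sim
    return build_mli_table(sim.products, lexicon)


@pytest.fixture(scope="session")
def small_profiles(small_sim, small_mli):
    _, sim = small_sim
    return build_profiles(sim.recalls, small_mli)
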