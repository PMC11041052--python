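import numpy as np
import pytest

from pclseg.agnet import AGNet, AGNetConfig
from pclseg.phantom import PhantomSpec, StudyRecord, generate_phantom


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic 64x64x32 phantom with three attached cysts."""
    return generate_phantom(PhantomSpec(seed=42, n_cysts=3))


@pytest.fixture(scope="session")
def control_pair():
    """A cyst-free phantom."""
    return generate_phantom(PhantomSpec(seed=43, n_cysts=0))


@pytest.fixture(scope="session")
def tiny_net_cfg():
    return AGNetConfig(n_scales=2, base_channels=4)


@pytest.fixture(scope="session")
def tiny_net(tiny_net_cfg):
    return AGNet(tiny_net_cfg, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_study(seed=0, n_cysts=1, split="train", risk="high"):
    ct, lab = generate_phantom(PhantomSpec(seed=seed, n_cysts=n_cysts))
    return StudyRecord(
        study_id=f"s{seed}", ct=ct, labels=lab, is_case=n_cysts > 0,
        risk_group=risk if n_cysts else "none", split=split)
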