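import copy

import numpy as np
import pytest

from crcdemand.cohort import demography_from_config
from crcdemand.parameters import priors_from_config, read_config
from crcdemand.runner import StudyConfig
from crcdemand.surveillance import policy_from_config


@pytest.fixture(scope="session")
def default_cfg() -> dict:
    return read_config()


@pytest.fixture(scope="session")
def study() -> StudyConfig:
    return StudyConfig.load()


def pointify(cfg: dict, adherence: float = 0.525) -> dict:
    """Replace every Beta prior by a point mass at its mean and pin adherence,
    giving a deterministic-parameter variant of a config."""
    cfg = copy.deepcopy(cfg)
    for v in cfg["screening"].values():
        if isinstance(v, dict) and "ess" in v:
            v["ess"] = None
    cfg["psa"]["adherence"] = {"low": adherence, "high": adherence}
    return cfg


def small_cfg(cfg: dict, size: int = 20_000, adherence: float = 0.525) -> dict:
    """A 1/5-scale deterministic-parameter config for fast tests."""
    cfg = pointify(cfg, adherence)
    scale = size / cfg["demography"]["initial_size"]
    cfg["demography"]["initial_size"] = size
    cfg["demography"]["entrants_first"] = int(cfg["demography"]["entrants_first"] * scale)
    cfg["demography"]["entrants_last"] = int(cfg["demography"]["entrants_last"] * scale)
    return cfg


@pytest.fixture()
def small_bundle(default_cfg):
    cfg = small_cfg(default_cfg)
    return (priors_from_config(cfg), demography_from_config(cfg),
            policy_from_config(cfg))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20150917)
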