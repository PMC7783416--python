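import dataclasses

import numpy as np
import pytest

import emosub
from emosub.config import CohortConfig


@pytest.fixture(scope="session")
def replication_cfg():
    return emosub.replication_config()


@pytest.fixture(scope="session")
def replication_run(replication_cfg):
    """One shared pipeline run at the published sample sizes (542 + 710)."""
    cfg = replication_cfg
    cfg = dataclasses.replace(cfg)
    cfg.analysis = dataclasses.replace(cfg.analysis, n_boot=200)
    return emosub.run_pipeline(cfg, seed=20260924)


@pytest.fixture
def small_cohort():
    cfg = CohortConfig(n_cd=120, n_tdc=160, seed=11)
    return emosub.generate_cohort(cfg, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
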