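"""Shared fixtures: small synthetic studies sized for fast tests."""

import numpy as np
import pytest

import evooscreen as es
from evooscreen.spectra import Sensor


def small_design(seed: int = 11, **overrides) -> es.StudyDesign:
    """A miniature study: same structure as the full design, far fewer
    samples and scans."""
    params = dict(
        n_evoo=8, n_rvoo=4, n_opo=3, n_other=4,
        n_mix_olive=4, n_mix_other=6,
        scans_per_run={Sensor.VIS: 3, Sensor.FLUO: 3, Sensor.NIR: 5},
        n_saturated_fluo=3, n_saturated_vis=2,
        seed=seed,
    )
    params.update(overrides)
    return es.StudyDesign(**params)


@pytest.fixture(scope="session")
def mini_design():
    return small_design()


@pytest.fixture(scope="session")
def mini_study(mini_design):
    return es.generate_study(mini_design)


@pytest.fixture(scope="session")
def mini_processed(mini_study):
    return es.process_study(mini_study)


@pytest.fixture(scope="session")
def full_processed():
    """The full-scale default study, processed once for the whole session."""
    study = es.generate_study(es.StudyDesign(seed=1))
    return es.process_study(study)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
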