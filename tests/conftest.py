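"""Shared fixtures: small synthetic sessions at reduced sampling rates.

All fixtures are generated programmatically; 250 Hz keeps every analysis
band edge (up to 55 Hz) well below Nyquist while making multi-seed batteries
fast.
"""

import warnings

import numpy as np
import pytest

from lfpmodes import AnalysisConfig, spec_for
from lfpmodes.experiments import SINGLE_STR_LAYOUT
from lfpmodes.simulate import make_session

FS = 250.0


@pytest.fixture(autouse=True)
def _quiet_baseline_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig(fs_target=FS)


@pytest.fixture(scope="session")
def mixed_session():
    """ZT13-like striatal session: both modes well represented."""
    spec = spec_for(13, "Str", fs=FS, duration=120.0, seed=101)
    return make_session(spec)


@pytest.fixture(scope="session")
def slow_session():
    """ZT1-like striatal session dominated by the slow oscillation."""
    spec = spec_for(1, "Str", fs=FS, duration=120.0, seed=202)
    return make_session(spec)


@pytest.fixture(scope="session")
def single_channel_mixed():
    spec = spec_for(13, "Str", fs=FS, duration=120.0, seed=303,
                    channel_layout=SINGLE_STR_LAYOUT)
    return make_session(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
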