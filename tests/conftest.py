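import numpy as np
import pytest

import colorcat as cc


@pytest.fixture(scope="session")
def sset():
    return cc.canonical_stimulus_set()


@pytest.fixture(scope="session")
def null_truth():
    return cc.GroundTruth("null", sigma=20.0, dprime=2.0)


@pytest.fixture(scope="session")
def null_table(sset, null_truth):
    return cc.generate_trials(null_truth, sset, 10000, seed=101)


@pytest.fixture(scope="session")
def scenarios(sset):
    """(cognitive, nonuniform) matched mechanism scenarios."""
    return cc.make_fig3_scenarios(sset)
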