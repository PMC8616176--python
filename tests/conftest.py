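import numpy as np
import pytest

from clonefit import datasets


@pytest.fixture(scope="session")
def times_12h():
    """Default sampling grid: every 12 h to 264 h."""
    return np.arange(0.0, 264.001, 12.0)


@pytest.fixture(scope="session")
def noiseless_competition_preset():
    """Default competition scenario with the measurement noise switched off."""
    s = datasets.FUSION_NEGATIVE
    r = datasets.FUSION_POSITIVE
    return datasets.CompetitionPreset(
        clone_s=datasets.ClonePreset(s.label, s.fusion_status, s.r, s.K, s.x0, 0.0),
        clone_r=datasets.ClonePreset(r.label, r.fusion_status, r.r, r.K, r.x0, 0.0),
        alpha_sr=datasets.COMPETITION_DEFAULT.alpha_sr,
        alpha_rs=datasets.COMPETITION_DEFAULT.alpha_rs,
    )


@pytest.fixture(scope="session")
def noiseless_coculture(noiseless_competition_preset):
    curves, truth = datasets.make_coculture(noiseless_competition_preset, seed=1)
    return curves, truth
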