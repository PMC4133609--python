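import numpy as np
import pytest

from profaln.profile_model import (AMINO_ACIDS, BackgroundModel, ProfileHMM,
                                   DEFAULT_TRANSITIONS)


@pytest.fixture
def uniform_bg():
    return BackgroundModel(np.full(20, 0.05))


@pytest.fixture
def default_bg():
    return BackgroundModel.default()


def make_profile(emissions, name="p", annotation=None):
    """Profile with given emission rows and default transitions."""
    emissions = np.atleast_2d(np.asarray(emissions, dtype=float))
    transitions = np.tile(DEFAULT_TRANSITIONS, (emissions.shape[0], 1))
    p = ProfileHMM(name=name, emissions=emissions, transitions=transitions)
    if annotation is not None:
        p.attach_annotation(annotation)
    return p


def one_hot(residue):
    row = np.zeros(20)
    row[AMINO_ACIDS.index(residue)] = 1.0
    return row


@pytest.fixture
def profile_factory():
    return make_profile
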