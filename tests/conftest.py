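import numpy as np
import pytest

from memtrace.synthetic_data import ToneTrial, TrialSequence


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_sequence(f1_values, f2_values, iti=1.4):
    """Hand-built TrialSequence with a constant inter-trial interval."""
    trials = []
    clock = 0.0
    for i, (f1, f2) in enumerate(zip(f1_values, f2_values)):
        if i > 0:
            clock = trials[-1].onset2 + iti
        trials.append(ToneTrial(index=i + 1, f1=float(f1), f2=float(f2),
                                onset1=clock, onset2=clock + 0.6,
                                iti=None if i == 0 else iti))
    return TrialSequence(trials)


@pytest.fixture
def toy_sequence():
    return make_sequence([1000, 1100, 900, 1050], [980, 1120, 890, 1030])
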