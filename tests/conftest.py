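import numpy as np
import pytest

from hcnfep.fep_io import LambdaSchedule, WindowSamples


@pytest.fixture
def schedule():
    return LambdaSchedule()


def make_window(index, du, leg="forward", delta_lambda=0.05):
    lo, hi = (index - 1) * delta_lambda, index * delta_lambda
    if leg == "backward":
        lo, hi = hi, lo
    return WindowSamples(index, lo, hi, np.asarray(du, dtype=float), leg)


@pytest.fixture
def make_window_factory():
    return make_window
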