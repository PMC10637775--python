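import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def match_peaks(detected, true, tol=1):
    """Greedy one-to-one matching of detected to true peak frames within tol."""
    detected = sorted(int(d) for d in detected)
    used = set()
    tp = 0
    for t in sorted(int(x) for x in true):
        for j, d in enumerate(detected):
            if j not in used and abs(d - t) <= tol:
                used.add(j)
                tp += 1
                break
    return tp


@pytest.fixture
def peak_matcher():
    return match_peaks
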