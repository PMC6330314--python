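import numpy as np
import pytest

from verticality.psychometric import pf_eval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simulate_trials():
    """Factory: Bernoulli 2AFC trials at uniformly placed stimuli."""

    def _simulate(rng, n, pse, jnd, lapse=0.02, lo=-45.0, hi=45.0):
        x = rng.uniform(lo, hi, size=n)
        p = pf_eval(x, pse, jnd, lapse)
        r = (rng.random(n) < p).astype(int)
        return x, r

    return _simulate
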