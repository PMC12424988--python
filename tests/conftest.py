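import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def planted_region(rng):
    """Noise-free 2-event region: patterns, lengths, and the V x T matrix."""
    from eventscales import make_event_patterns, simulate_timecourse

    patterns = make_event_patterns(2, 40, rng)
    lengths = np.array([12, 8])
    data = simulate_timecourse(patterns, lengths, 0.0, rng)
    return patterns, lengths, data
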