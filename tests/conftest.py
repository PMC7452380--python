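import numpy as np
import pytest

from lucifit import SimParams, TimeSeries


@pytest.fixture
def clean_params() -> SimParams:
    """Noiseless default recording: 24 h LD + 96 h DD at 1-h sampling."""
    return SimParams(noise_model="none")


@pytest.fixture
def short_series() -> TimeSeries:
    """A tiny 6-point series for I/O and trimming tests."""
    return TimeSeries(
        sample_id="w1",
        times_h=np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0]),
        counts_cps=np.array([10.0, 12.0, 9.0, 11.0, 10.5, 10.0]),
        dd_onset_h=2.0,
    )
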