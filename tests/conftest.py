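import numpy as np
import pytest

from breathomics.pleth import PressureTrace, calibrate, integrate_flow, segment_breaths
from breathomics.synthgen import BreathSimParams, ExprPairSimParams, gen_breath_trace


@pytest.fixture(scope="session")
def breath_study():
    """One 600 s recording at the standard study conditions, fully analysed."""
    trace, cal_trace, truth = gen_breath_trace(BreathSimParams(seed=11))
    cal = calibrate(cal_trace)
    series = segment_breaths(integrate_flow(trace))
    return trace, cal, series, truth


@pytest.fixture(scope="session")
def clean_periodic_trace():
    """Noiseless, jitter-free 3 Hz breathing over 10 s (30 breaths)."""
    return gen_breath_trace(
        BreathSimParams(
            duration_s=10.0,
            noise_sd=0.0,
            ibi_cv=0.0,
            amp_cv=0.0,
            p_apnea=0.0,
            vf_mean=180.0,
            seed=0,
        )
    )


@pytest.fixture(scope="session")
def expr_pair():
    """Paired expression studies at the generator defaults."""
    from breathomics.synthgen import gen_expression_pair

    return gen_expression_pair(ExprPairSimParams(seed=5))


def flat_trace(duration_s=30.0, fs=1000.0, label="room_air"):
    n = int(duration_s * fs)
    return PressureTrace(
        samples=np.zeros(n),
        sampling_rate_hz=fs,
        epochs=[(label, 0.0, duration_s)],
    )
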