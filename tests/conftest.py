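import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from amds.assay_model import FluorescenceTrace, ThresholdSet, baseline_correct


def make_trace(values, times=None, well_id=1, channel="F1", corrected=False):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(len(values), dtype=float)
    tr = FluorescenceTrace(well_id, channel, np.asarray(times, float), values)
    return baseline_correct(tr) if corrected else tr


@pytest.fixture
def thresholds():
    """Plain threshold set: FNT=100, RPT=0.6, EP=600 s, JP=300 s."""
    return ThresholdSet(FNT=100.0, RPT=0.6)


@pytest.fixture
def saturating_trace():
    """Noise-free saturating reaction spanning the full detection window."""
    t = np.arange(0.0, 601.0)
    return make_trace(500.0 * (1.0 - np.exp(-0.02 * t)), times=t, corrected=True)


@pytest.fixture
def drifting_trace():
    """Pure linear background drift over the window."""
    t = np.arange(0.0, 601.0)
    return make_trace(0.5 * t, times=t, corrected=True)
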