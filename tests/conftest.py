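import numpy as np
import pytest

from rehabtap import synthetic
from rehabtap.trace_io import ForceTrace


@pytest.fixture
def clean_params():
    """Zero-noise, artifact-free generator settings (degenerate oracle case)."""
    return synthetic.TapGenParams(
        noise_sd_n=0.0, soft_tap_rate=0.0, double_tap_rate=0.0, pause_rate=0.0,
        mean_iti_ms=300.0, iti_cv=0.0, duration_s=10.0,
    )


@pytest.fixture
def newton_trace():
    """Short flat trace in Newtons for contract checks."""
    return ForceTrace(samples=np.zeros(3000), sample_rate_hz=3000.0, units="newton")


@pytest.fixture
def small_cohort():
    return synthetic.generate_cohort(synthetic.CohortGenParams(n_per_group=6, seed=123))
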