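import numpy as np
import pytest

from respigate.dosimetry import ReferencePlanParams, build_reference_dose
from respigate.synthetic import WaveformSpec, generate_trace


def make_spec(**kwargs) -> WaveformSpec:
    """A clean raised-cosine spec: no drift, no variability, no noise."""
    defaults = dict(duration_s=60.0, sample_rate_hz=30.0,
                    base_amplitude_mm=(4.0, 10.0, 2.5), base_period_s=3.0,
                    amplitude_cv=0.0, period_cv=0.0, noise_sd_mm=0.0, seed=0)
    defaults.update(kwargs)
    return WaveformSpec(**defaults)


@pytest.fixture
def clean_trace():
    """Stationary noiseless breathing trace, CC amplitude 10 mm, period 3 s."""
    return generate_trace(make_spec())


@pytest.fixture
def drifting_trace():
    """Noiseless trace with a constant downward CC baseline drift."""
    return generate_trace(make_spec(
        drift_rate_mm_per_s=(-0.15, -0.3, -0.1), duration_s=90.0))


@pytest.fixture(scope="session")
def reference_dose():
    """Default analytic reference plan on the standard 81^3 / 1 mm grid."""
    return build_reference_dose(ReferencePlanParams())


@pytest.fixture(scope="session")
def coarse_reference_dose():
    """Small grid for oracle comparisons (31^3 voxels, 2.5 mm spacing)."""
    return build_reference_dose(ReferencePlanParams(), shape=(31, 31, 31),
                                spacing_mm=2.5)
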