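import numpy as np
import pytest

from voltgrade import PeakModel, simulate_voltammogram
from voltgrade.clinical import load_packaged_cohort


def make_gaussian_trace(
    amplitude=2.0,
    center=-0.25,
    sd=0.04,
    n_points=1024,
    baseline_intercept=0.0,
    baseline_slope=0.0,
    e_start=-0.05,
    e_end=-0.45,
    scan_rate=0.05,
):
    """Noiseless single-Gaussian sweep used as the analytic oracle signal."""
    model = PeakModel(
        baseline_intercept=baseline_intercept,
        baseline_slope=baseline_slope,
        peak_center=center,
        peak_sd=sd,
        peak_amplitude=amplitude,
        noise_sd=0.0,
        n_points=n_points,
        e_start=e_start,
        e_end=e_end,
        scan_rate=scan_rate,
    )
    return simulate_voltammogram(model, seed=0)


@pytest.fixture
def gaussian_trace():
    return make_gaussian_trace()


@pytest.fixture(scope="session")
def cohort():
    return load_packaged_cohort()
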