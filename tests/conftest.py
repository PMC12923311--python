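import numpy as np
import pytest

from nbceus.datatypes import AcquisitionSchedule
from nbceus.synthetic import (
    DESK_SCHEDULE,
    RenderParams,
    TruthParams,
    generate_cohort,
    generate_kidney_mask,
    generate_truth,
    render_cine,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def mask_map():
    return generate_kidney_mask(64, 64, seed=1)


@pytest.fixture(scope="session")
def desk_cohort():
    """One default-scale cohort (4 sham-like + 6 injury-like animals)."""
    return generate_cohort(4, 6, seed=2024)


@pytest.fixture(scope="session")
def noise_free_series():
    """Vascular-only, noise-free render with on-grid peak times.

    One 120-s acquisition at 5 fps; every pixel's TIC is then the pure
    gamma-variate bolus, so peak recovery is exact.
    """
    mm = generate_kidney_mask(32, 32, seed=3)
    truth = generate_truth(mm, "sham", seed=4)
    truth.peak_time_s[:] = 10.0  # exactly on the 0.2-s sample grid
    truth.retention_weight[:] = 0.0
    schedule = AcquisitionSchedule(n_acquisitions=1, frames_per_acquisition=600, frame_interval_s=0.2)
    series = render_cine(
        truth,
        schedule,
        RenderParams(sigma_mult=0.0, sigma_add=0.0),
        seed=5,
    )
    return series, truth
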