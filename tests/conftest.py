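import numpy as np
import pytest

from dynamrs.datatypes import AcquisitionParams, SpectrumSeries


@pytest.fixture
def params():
    """Standard glucose-experiment acquisition parameters."""
    return AcquisitionParams()


@pytest.fixture
def params_no_dead_time():
    return AcquisitionParams(dead_time_points=0)


@pytest.fixture
def flat_noise_spectrum():
    """Signal-free 1000-bin spectrum of unit Gaussian noise."""
    rng = np.random.default_rng(7)
    n = 1000
    return SpectrumSeries(
        data=rng.normal(0.0, 1.0, (1, n)),
        ppm=np.linspace(200.0, 0.0, n),
        frame_times=[1.0],
        reference_ppm=100.0,
        mode="phased",
    )


def make_real_spectrum(values, n_frames=1):
    """Wrap a real 1-D array as a phased SpectrumSeries on a 200..0 ppm axis."""
    values = np.atleast_2d(values)
    n = values.shape[1]
    return SpectrumSeries(
        data=np.repeat(values, n_frames, axis=0) if values.shape[0] == 1 else values,
        ppm=np.linspace(200.0, 0.0, n),
        frame_times=np.arange(1, max(n_frames, values.shape[0]) + 1, dtype=float),
        reference_ppm=100.0,
        mode="phased",
    )
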