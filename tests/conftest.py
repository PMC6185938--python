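import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", max_examples=25, derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_free_config():
    """Simulator conditions under which recovery must be exact."""
    from ciliaquant import SimulationConfig

    return SimulationConfig(
        n_nuclei=15,
        psf_sigma_um=0.0,
        read_noise_sd=0.0,
        shot_noise=False,
    )


@pytest.fixture
def absolute_segmentation():
    """Absolute-threshold configs suited to the noise-free simulator output
    (background 100, structures up to 500)."""
    from ciliaquant import HysteresisParams, SegmentationConfig

    cilia = SegmentationConfig(
        hysteresis=HysteresisParams(140, 180, "absolute"),
        min_object_area_px=5,
        split_min_distance_px=5,
    )
    nuclei = SegmentationConfig(
        hysteresis=HysteresisParams(140, 180, "absolute"),
        min_object_area_px=50,
        split_min_distance_px=10,
    )
    return cilia, nuclei
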