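import numpy as np
import pytest

from optophen import roi_features as rf
from optophen.spatial_io import map_barcode_to_image
from optophen.synthgen import (
    SynthConfig,
    simulate_dataset,
    texture_coded_config,
)


@pytest.fixture(scope="session")
def small_dataset():
    """An 8x8-grid texture-coded dataset shared across tests."""
    cfg = texture_coded_config(seed=11, grid_shape=(8, 8))
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_centers(small_dataset):
    ds = small_dataset
    mapped = map_barcode_to_image(ds.barcodes, image_shape=ds.stack.shape, roi_size=70)
    return mapped


@pytest.fixture(scope="session")
def small_rois(small_dataset, small_centers):
    ds = small_dataset
    return rf.extract_rois(
        ds.stack.data, small_centers[["x", "y"]].to_numpy(), size=70
    )


@pytest.fixture(scope="session")
def flat_dataset():
    """Noise-free dataset: constant intensity inside each disc."""
    cfg = SynthConfig(
        grid_shape=(3, 3),
        n_clusters=1,
        channel_means=np.array([[3000.0, 4000.0, 5000.0, 6000.0, 7000.0]]),
        texture_amplitude=0.0,
        noise_amplitude=0.0,
        illumination_amplitude=0.0,
        seed=7,
    )
    return simulate_dataset(cfg)
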