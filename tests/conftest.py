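import numpy as np
import pytest

from volseg import filters, supervoxels, synthetic


@pytest.fixture(scope="session")
def blob_phantom():
    """Standard 64^3 two-class blob phantom: fg 0.8, bg 0.2, noise sigma 0.05."""
    spec = synthetic.PhantomSpec(
        shape=(64, 64, 64), n_objects=5, fg_intensity=0.8, bg_intensity=0.2,
        noise_sigma=0.05, seed=7,
    )
    volume, truth, centroids = synthetic.generate_phantom(spec)
    return volume, truth, centroids


@pytest.fixture(scope="session")
def blob_partition(blob_phantom):
    """Supervoxels of the standard phantom, computed on a TV-denoised volume."""
    volume, _, _ = blob_phantom
    denoised = filters.apply_filter(volume, filters.FilterSpec("total_variation", {"weight": 0.2}))
    return supervoxels.compute_supervoxels(
        np.clip(denoised, 0, 1), supervoxels.SupervoxelParams((10, 10, 10))
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
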