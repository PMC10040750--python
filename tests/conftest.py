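import numpy as np
import pytest

from bladnet import phantom as ph
from bladnet.model import BLSConfig, PipelineConfig
from bladnet.preprocess import PreprocessConfig
from bladnet.slice_cnn import ExtractorConfig


@pytest.fixture(scope="session")
def small_spec():
    """Desk-size phantom spec: 24x24x16 at 6 mm voxels, 2 zero end slices.

    The coarse spacing keeps the 8 mm FWHM smoothing kernel narrow in voxel
    units, so the disease signal survives at this resolution.
    """
    return ph.PhantomSpec(shape=(24, 24, 16), spacing=(6.0, 6.0, 6.0), n_zero_end_slices=2)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Pipeline config matched to the small phantom spec: 16x16x16 grid,
    12 retained slices -> 4 groups x 3 channels."""
    return PipelineConfig(
        preprocess=PreprocessConfig(shape=(16, 16, 16)),
        extractor=ExtractorConfig(
            channels_per_group=3,
            conv_widths=(4, 8),
            feature_dim_per_group=4,
            epochs=4,
            batch_size=8,
            seed=17,
        ),
        bls=BLSConfig(n_feature_nodes=20, n_enhance_nodes=20, initial_blocks=1, seed=7),
        seed=0,
    )


@pytest.fixture(scope="session")
def tiny_groups(small_spec, tiny_cfg):
    """24 preprocessed phantoms (8 per class, AD/MCI/CN) with labels."""
    from bladnet.preprocess import preprocess_volume

    groups, labels = [], []
    for i in range(24):
        label = ["AD", "MCI", "CN"][i % 3]
        v = ph.generate_phantom(label, small_spec, seed=500 + i)
        groups.append(preprocess_volume(v, tiny_cfg.preprocess))
        labels.append(label)
    return groups, labels


@pytest.fixture(scope="session")
def blob_features():
    """Two well-separated Gaussian blobs (separation 10 sigma), n=100."""
    rng = np.random.default_rng(42)
    X = np.vstack(
        [rng.normal(0.0, 1.0, size=(50, 12)), rng.normal(10.0, 1.0, size=(50, 12))]
    )
    labels = ["neg"] * 50 + ["pos"] * 50
    return X, labels
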