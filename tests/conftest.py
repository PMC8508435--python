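import numpy as np
import pytest

from melcaps.architecture import ArchitectureSpec, LayerSpec
from melcaps.synthetic import SyntheticDatasetSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def lesion_dataset_48():
    """Small easy (difficulty 0) two-class lesion set at 48 px."""
    spec = SyntheticDatasetSpec(
        n_per_class=30, image_size=(48, 48), difficulty=0.0, noise_sd=0.02, seed=11
    )
    return generate_dataset(spec)


@pytest.fixture
def tiny_spec():
    """A minimal trainable spec (12 px input) exercising every layer kind."""
    layers = [
        LayerSpec("conv2d_1", "conv", (3, 3), 2, "valid", 4),
        LayerSpec("batch_normalization_1", "batchnorm"),
        LayerSpec("activation_1", "activation"),
        LayerSpec("conv2d_2", "conv", (3, 3), 1, "same", 4),
        LayerSpec("max_pooling2d_1", "maxpool", (3, 3), 2, "valid"),
        LayerSpec("primary_capsule_reshape", "reshape", width=4),
        LayerSpec("primary_capsule_squash", "caps_squash"),
        LayerSpec(
            "digit_capsule",
            "capsule_layer",
            width=6,
            params={"num_classes": 2, "routing_iterations": 1},
        ),
        LayerSpec("output_capsule", "length"),
    ]
    return ArchitectureSpec(
        layers=layers, primary_caps_dim=4, class_caps_features=6, input_shape=(12, 12, 3)
    )
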