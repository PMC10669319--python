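import numpy as np
import pytest

from epoadl import backbone as bb
from epoadl import synthdata as sd


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic patch set (150 images, 75 per class)."""
    return sd.generate_dataset(sd.SynthConfig(seed=0))


@pytest.fixture(scope="session")
def separable_patches():
    """Two trivially separable classes: solid dark vs solid light patches."""
    rng = np.random.default_rng(7)
    dark = rng.integers(20, 80, (40, 64, 64, 3), dtype=np.uint8)
    light = rng.integers(170, 230, (40, 64, 64, 3), dtype=np.uint8)
    images = np.concatenate([dark, light])
    labels = np.array([0] * 40 + [1] * 40)
    return images, labels


@pytest.fixture(scope="session")
def trained_desk_backbone(separable_patches):
    """Desk-scale backbone trained on the separable patches."""
    images, labels = separable_patches
    model = bb.build_backbone(bb.BackboneConfig.desk(), seed=0)
    history = bb.train_backbone(
        model, images, labels, bb.TrainHyperparams(epochs=5, seed=0)
    )
    return model, history, images, labels
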