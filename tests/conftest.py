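import numpy as np
import pytest

from imcseg.net import NetConfig, UNet, train
from imcseg.synthetic import CellType, SceneParams, generate_scene, make_training_set


def tiny_scene_params(seed: int = 7, **overrides) -> SceneParams:
    """64x64 scene with a handful of cells; fast to generate and segment."""
    kwargs = dict(height=64, width=64, n_cells=6, radius_range=(4.0, 7.0),
                  min_gap=3.0, seed=seed)
    kwargs.update(overrides)
    return SceneParams(**kwargs)


@pytest.fixture
def tiny_scene():
    return generate_scene(tiny_scene_params())


@pytest.fixture(scope="session")
def tiny_model():
    """A small U-Net trained briefly on 32x32 patches of synthetic scenes.

    Deliberately modest: enough training that cell interiors score higher
    foreground probability than background, which is all the fast tests need.
    """
    cfg = NetConfig(depth=2, base_filters=8, patch_size=32, batch_size=8,
                    max_epochs=12, early_stop_patience=12,
                    validation_fraction=0.15, seed=0)
    examples = make_training_set(
        [tiny_scene_params(seed=100 + i) for i in range(10)], patch_size=32
    )
    model = UNet(cfg)
    train(model, examples, cfg)
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
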