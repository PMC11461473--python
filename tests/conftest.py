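import numpy as np
import pytest

from smlsyolo.data import SynthConfig, generate_synthetic_samples

try:
    from hypothesis import settings
    settings.register_profile("ci", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synth_samples():
    """Small deterministic synthetic fundus set shared across tests."""
    return generate_synthetic_samples(
        SynthConfig(n_images=6, image_size=96, seed=3))


@pytest.fixture(scope="session")
def overfit_run():
    """One desk-scale training run shared by the training/acceptance tests.

    Trains the small model variant on 8 synthetic 256x256 fundus images and
    returns (model, samples, loss history, train config).
    """
    from smlsyolo.model import build_model, tiny_config
    from smlsyolo.training import TrainConfig, train

    samples = generate_synthetic_samples(
        SynthConfig(n_images=8, image_size=256, seed=0))
    model = build_model(tiny_config(), seed=0)
    cfg = TrainConfig(image_size=256, batch_size=8, max_steps=450,
                      mosaic_prob=0.0, seed=0, lr0=0.01)
    history = train(model, samples, cfg, log_every=0)
    return model, samples, history, cfg
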