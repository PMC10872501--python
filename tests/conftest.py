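import numpy as np
import pytest

from neurofuse.networks import EncoderConfig, HeadConfig, build_modality_model
from neurofuse.synthdata import GeneratorConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """64-subject paired dataset with the default planted structure."""
    return generate_dataset(GeneratorConfig(n_subjects=64, seed=7))


@pytest.fixture(scope="session")
def tiny_models():
    """Untrained desk-scale modality pair (deterministic init)."""
    cfg = EncoderConfig.desk()
    head = HeadConfig(global_depth=1, head_dim=cfg.latent_dim)
    r = np.random.default_rng(0)
    return {m: build_modality_model(cfg, head, r, modality_id=m) for m in (1, 2)}


def finite_difference_grad(f, x, eps=1e-6):
    """Central finite differences of a scalar function of an array."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        hi = f(x)
        x[idx] = orig - eps
        lo = f(x)
        x[idx] = orig
        g[idx] = (hi - lo) / (2 * eps)
    return g
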