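import numpy as np
import pytest

from coretr import ModelConfig, PhantomSpec, generate_phantom, preprocess


@pytest.fixture(scope="session")
def tiny_cfg() -> ModelConfig:
    return ModelConfig.tiny()


@pytest.fixture(scope="session")
def small_phantom():
    """One noise-free 32^3 phantom with a single mid-sized tumor."""
    spec = PhantomSpec(dims=(32, 32, 32), spacing=(2.0, 2.0, 2.0), n_tumors=1,
                       tumor_radii_mm=(5.0, 7.0), noise_sd=0.0, seed=42)
    vol, seg = generate_phantom(spec)
    return vol, seg, spec


@pytest.fixture(scope="session")
def small_phantom_preprocessed(small_phantom):
    vol, seg, spec = small_phantom
    return preprocess(vol), seg, spec


def rand_mask(rng: np.random.Generator, shape=(10, 10, 10), p=0.2) -> np.ndarray:
    """Random blobby binary mask (union of a few small boxes + salt)."""
    m = rng.random(shape) < p * 0.3
    for _ in range(rng.integers(1, 4)):
        c = [rng.integers(0, s) for s in shape]
        r = [int(rng.integers(1, max(s // 3, 2))) for s in shape]
        sl = tuple(slice(max(c[i] - r[i], 0), min(c[i] + r[i] + 1, shape[i]))
                   for i in range(3))
        m[sl] = True
    return m.astype(np.uint8)
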