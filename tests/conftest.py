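import numpy as np
import pytest

import tamunet.nn as nn


def gradcheck(f, tensors, eps=1e-2, tol=1e-2, seed=0):
    """Central finite-difference check of reverse-mode gradients.

    The objective is <f(), g> for a fixed random cotangent g, accumulated in
    float64 (the engine itself is float32).
    """
    for t in tensors:
        t.grad = None
    out = f()
    g = np.random.default_rng(seed).standard_normal(out.shape).astype(np.float32)
    out.backward(g.copy())

    def obj():
        return float((f().data.astype(np.float64) * g).sum())

    for t in tensors:
        ana = t.grad.copy()
        num = np.zeros_like(t.data, dtype=np.float64)
        it = np.nditer(t.data, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = float(t.data[idx])
            t.data[idx] = orig + eps
            f1 = obj()
            t.data[idx] = orig - eps
            f0 = obj()
            t.data[idx] = orig
            num[idx] = (f1 - f0) / (2 * eps)
        scale = max(1e-6, float(np.abs(num).max()))
        err = float(np.abs(ana - num).max()) / scale
        assert err < tol, f"gradient mismatch: relative error {err:.3g}"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One small deterministic phantom pair reused across tests."""
    from tamunet.phantoms import PhantomConfig, make_phantom_volume

    cfg = PhantomConfig(volume_shape=(24, 48, 48), spacing=(2.5, 1.5, 1.5),
                        liver_semiaxes=(18.0, 22.0, 25.0), seed=7,
                        case_id="fixture-case")
    return make_phantom_volume(cfg)


@pytest.fixture(scope="session")
def tiny_samples(small_phantom):
    """Preprocessed 32x32 slice samples of the fixture phantom."""
    from tamunet.preprocessing import preprocess_volume

    vol, lab = small_phantom
    return preprocess_volume(vol, lab, target=32)
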