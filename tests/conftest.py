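import numpy as np
import pytest

from lmsaunet.synthetic import SyntheticSpec, generate_sample


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def synthetic_sample():
    """One deterministic 64x64 image/mask pair."""
    spec = SyntheticSpec()
    img, mask, prov = generate_sample(spec, spec.sample_seed(11, 0))
    return img.astype(np.float32), mask


def numeric_gradcheck(fn, *arrays, eps=1e-6, tol=1e-5, seed=0):
    """Compare analytic gradients of fn(*tensors) against central differences."""
    import lmsaunet.autograd as ag

    local = np.random.default_rng(seed)
    tensors = [ag.Tensor(np.array(a, dtype=np.float64), requires_grad=True)
               for a in arrays]
    out = fn(*tensors)
    w = local.standard_normal(out.data.shape)
    ag.tsum(ag.mul(out, w)).backward()

    for t in tensors:
        flat = t.data.ravel()
        num = np.zeros_like(flat)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            up = (fn(*[ag.Tensor(u.data) for u in tensors]).data * w).sum()
            flat[i] = orig - eps
            dn = (fn(*[ag.Tensor(u.data) for u in tensors]).data * w).sum()
            flat[i] = orig
            num[i] = (up - dn) / (2 * eps)
        scale = max(1.0, np.abs(num).max())
        np.testing.assert_allclose(t.grad.ravel(), num, atol=tol * scale,
                                   err_msg=f"gradient mismatch for input {t.shape}")
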