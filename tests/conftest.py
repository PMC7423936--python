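import numpy as np
import pytest

from spread_dti import FieldSpec, LesionSpec, generate_pair


@pytest.fixture
def small_spec():
    """A 16^3 grid: large enough for bandwidth-2 kernels, fast to permute."""
    return FieldSpec(shape=(16, 16, 16), mask_margin=3, noise_sd=0.02, seed=7)


@pytest.fixture
def small_pair(small_spec):
    return generate_pair(small_spec)


@pytest.fixture
def lesioned_pair_factory():
    """Factory for noise-free pairs with a single centered lesion."""

    def make(shape=(20, 20, 20), radius=3.0, delta=-0.1, noise_sd=0.0, seed=3):
        spec = FieldSpec(shape=shape, mask_margin=3, noise_sd=noise_sd, seed=seed)
        center = tuple(n // 2 for n in shape)
        lesion = LesionSpec(center=center, radius_vox=radius, delta_fa=delta)
        return generate_pair(spec, [lesion]), lesion

    return make


def brute_force_nw(values, foreground, bandwidth, cutoff):
    """O(n^2) double-loop Nadaraya-Watson oracle with spherical truncation."""
    shape = values.shape
    out = np.zeros(shape)
    coords = np.argwhere(foreground)
    for v in coords:
        num = den = 0.0
        for u in coords:
            d2 = float(np.sum((u - v) ** 2))
            if d2 <= cutoff**2:
                w = np.exp(-d2 / (2.0 * bandwidth**2))
                num += w * values[tuple(u)]
                den += w
        out[tuple(v)] = num / den
    return out
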