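import dataclasses

import numpy as np
import pytest

from retquant.imgquant import segment_layers
from retquant.synthgen import (
    RetinaPhantomSpec,
    make_retina_phantom,
    random_sprouts,
)


def straight_sprout(spec: RetinaPhantomSpec, length_um: float, col_um: float = 100.0):
    """Vertical sprout rising from the first OPL row into the ONL."""
    start = spec.layer_boundaries[2] * spec.pixel_size_um
    return ((start, col_um), (start - length_um, col_um))


@pytest.fixture(scope="session")
def noiseless_spec():
    spec = RetinaPhantomSpec(noise_sigma=0.0)
    return dataclasses.replace(spec, sprouts=(straight_sprout(spec, 50.0),))


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return make_retina_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def noisy_phantoms():
    """20 seeded phantoms with 1-10 random sprouts each, at default noise."""
    out = []
    for seed in range(20):
        rng = np.random.default_rng(seed + 100)
        base = RetinaPhantomSpec(seed=seed)
        n = int(rng.integers(1, 11))
        spec = dataclasses.replace(base, sprouts=random_sprouts(n, base, rng))
        out.append((spec, *make_retina_phantom(spec)))
    return out


def masks_from_stack(stack, pixel_size_um=0.5):
    return segment_layers(
        stack[0], [stack[2]], is_marker_channel=stack[3], pixel_size_um=pixel_size_um
    )
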