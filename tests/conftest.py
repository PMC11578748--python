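import numpy as np
import pytest

from sproutnet.synth import SceneSpec, gen_field_image


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_boxes(rng, n, lo=0.0, hi=100.0):
    """n random valid xyxy boxes inside [lo, hi]²."""
    pts = rng.uniform(lo, hi, (n, 2, 2))
    lo_pts = pts.min(axis=1)
    hi_pts = pts.max(axis=1)
    return np.concatenate([lo_pts, hi_pts], axis=1)


@pytest.fixture(scope="session")
def small_scenes():
    """Eight deterministic 160px scenes with labels."""
    out = []
    for i in range(8):
        img, labels, _ = gen_field_image(SceneSpec(seed=100 + i))
        out.append((img, labels))
    return out
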