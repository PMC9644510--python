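import numpy as np
import pytest

from ihcscreen.synthetic import SyntheticSpec, generate_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_rgb(rng):
    """A 48x48 random-noise RGB image (uint8)."""
    return rng.integers(0, 256, (48, 48, 3), dtype=np.uint8)


@pytest.fixture(scope="session")
def synthetic_medium():
    """One noise-free 128px medium-expression synthetic image."""
    spec = SyntheticSpec(width=128, height=128, n_nuclei=20, seed=3)
    return generate_image(spec, "medium")


def make_level_channels(width=256, size_hint=64, per_level=6, seed0=0):
    """Noise-free protein OD channels for all three levels (test helper)."""
    channels, labels = [], []
    for li, lev in enumerate(("low", "medium", "high")):
        for s in range(per_level):
            img = generate_image(
                SyntheticSpec(width=width, height=width, n_nuclei=20, seed=seed0 + li * 100 + s),
                lev,
            )
            channels.append(img.protein_od_truth)
            labels.append(lev)
    return channels, labels
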