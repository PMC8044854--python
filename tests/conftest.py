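import numpy as np
import pytest

from gadnet.dataset import CellImage
from gadnet.synthetic import SynthConfig, generate_micrograph


@pytest.fixture(scope="session")
def small_dataset():
    """A small seeded micrograph with truth and annotations, shared read-only."""
    cfg = SynthConfig(n_cells=80, image_size=(360, 360), seed=7)
    stack, truth, annotations = generate_micrograph(cfg)
    return cfg, stack, truth, annotations


def make_crops(n, seed, h=12, w=12, channels=("gad67",), separable=True):
    """Synthetic labeled crops: bright (positive) vs dim (negative) interiors."""
    rng = np.random.default_rng(seed)
    crops = []
    for i in range(n):
        positive = i % 2 == 0
        mean = 0.8 if (positive and separable) else 0.2
        hh = int(rng.integers(h - 3, h + 4))
        ww = int(rng.integers(w - 3, w + 4))
        values = rng.normal(mean, 0.05, size=(len(channels), hh, ww))
        crops.append(
            CellImage(
                values=values.astype(np.float32),
                channels=tuple(channels),
                cell_id=i,
                label="positive" if positive else "negative",
            )
        )
    return crops
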