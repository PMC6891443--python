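import numpy as np
import pytest

from dermfocus.image import RawImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_gray(rng):
    """A random 16x16 float image in [0, 255]."""
    return rng.uniform(0.0, 255.0, size=(16, 16))


@pytest.fixture
def constant_rgb():
    """A mid-gray 220x220 RGB frame (large enough for the standard crop)."""
    return RawImage(np.full((220, 220, 3), 128, dtype=np.uint8))


def make_two_class_table(n_per_class=30, gap=(1.0, 2.0), seed=0, label_names=("neg", "pos")):
    """Feature table separable on column A with a known threshold gap."""
    import pandas as pd

    r = np.random.default_rng(seed)
    neg = pd.DataFrame(
        {
            "A": r.uniform(gap[1], gap[1] + 1.0, n_per_class),
            "B": r.normal(size=n_per_class),
            "label": label_names[0],
        }
    )
    pos = pd.DataFrame(
        {
            "A": r.uniform(gap[0] - 1.0, gap[0], n_per_class),
            "B": r.normal(size=n_per_class),
            "label": label_names[1],
        }
    )
    return pd.concat([neg, pos], ignore_index=True)
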