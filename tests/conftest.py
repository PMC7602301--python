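import numpy as np
import pytest

from m5cpred import LabeledDataset, RNAFragment

NUCS = "ACGU"


def random_window(rng: np.random.Generator, lambda_flank: int = 20,
                  n_prob: float = 0.0) -> str:
    """Random window with central C; optional per-position chance of 'N'."""
    width = 2 * lambda_flank + 1
    chars = list("ACGUN" if n_prob > 0 else NUCS)
    probs = None
    if n_prob > 0:
        probs = [(1 - n_prob) / 4] * 4 + [n_prob]
    draw = rng.choice(chars, size=width, p=probs)
    draw[lambda_flank] = "C"
    return "".join(draw)


def make_fragment(window: str, lambda_flank: int = 20,
                  parent_id: str = "frag") -> RNAFragment:
    return RNAFragment(parent_id=parent_id, center_pos_1based=lambda_flank + 1,
                       window=window, lambda_flank=lambda_flank)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def random_fragments(rng):
    """100 random lambda=20 fragments, ~10% of them containing 'N' runs."""
    frags = []
    for i in range(100):
        n_prob = 0.15 if i % 10 == 0 else 0.0
        frags.append(make_fragment(random_window(rng, n_prob=n_prob),
                                   parent_id=f"r{i}"))
    return frags


@pytest.fixture
def small_dataset(rng) -> LabeledDataset:
    """20 random fragments, 10 per class (no planted signal)."""
    frags = [make_fragment(random_window(rng), parent_id=f"d{i}") for i in range(20)]
    labels = np.array([1] * 10 + [0] * 10)
    return LabeledDataset(fragments=frags, labels=labels, lambda_flank=20)
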