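from pathlib import Path

import numpy as np
import pytest

from twindhmr.simulate import synthesize_pair_samples

DATA = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_samples(n_pairs: int, seed: int = 7, zygosity: str = "MZ"):
    return synthesize_pair_samples(
        n_pairs, zygosity, np.random.default_rng(seed)
    )
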