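import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from emscore import BoundaryMap, ContingencyTable, EvalMask, LabelImage


@pytest.fixture
def worked_gt() -> BoundaryMap:
    """4x4 two-segment micro-example: an 8-pixel and a 4-pixel cell separated
    by a one-pixel vertical border (12 foreground pixels)."""
    return BoundaryMap(np.array([[1, 1, 0, 1]] * 4))


@pytest.fixture
def all_ones_pred(worked_gt) -> BoundaryMap:
    """The all-merged prediction for the micro-example."""
    return BoundaryMap(np.ones(worked_gt.shape, dtype=np.uint8))


def random_label_pair(rng: np.random.Generator, shape=(16, 16), n_labels=6):
    """A random (pred, truth) pair of fully-labeled images."""
    pred = LabelImage(rng.integers(1, n_labels + 1, size=shape))
    truth = LabelImage(rng.integers(1, n_labels + 1, size=shape))
    return pred, truth, EvalMask.full(shape)


def random_table(rng: np.random.Generator, shape=(5, 5), max_count=9) -> ContingencyTable:
    """A random sparse contingency table with positive total count."""
    counts = rng.integers(0, max_count + 1, size=shape)
    if counts.sum() == 0:
        counts[0, 0] = 1
    entries = {
        (i + 1, j + 1): int(c)
        for (i, j), c in np.ndenumerate(counts)
        if c > 0
    }
    return ContingencyTable.from_counts(entries)
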