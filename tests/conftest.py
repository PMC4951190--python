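import numpy as np
import pytest

from synclust import SpineDataset, SpineSegment


@pytest.fixture
def worked_example_segment() -> SpineSegment:
    """The worked-example toy: 30 spines at unit spacing, 5 positives.

    Four positives at indices 10, 12, 13, 15 form one ensemble under a
    nearest-neighbor criterion of 2 units (6 spines within the span,
    one gap spine on each side); the positive at index 3 is isolated.
    """
    marks = np.zeros(30, dtype=bool)
    marks[[3, 10, 12, 13, 15]] = True
    return SpineSegment("cell0", "seg0", np.arange(30.0), marks)


def unit_lattice(n: int, positive_indices=()) -> SpineSegment:
    """A segment with ``n`` spines at unit spacing."""
    marks = np.zeros(n, dtype=bool)
    if len(positive_indices):
        marks[list(positive_indices)] = True
    return SpineSegment("cell0", "lat", np.arange(float(n)), marks)


@pytest.fixture
def lattice():
    return unit_lattice


@pytest.fixture
def small_dataset() -> SpineDataset:
    """Two short segments with a handful of positives each."""
    s1 = SpineSegment(
        "c1", "s1", np.array([0.0, 1.0, 2.5, 4.0, 10.0, 15.0]),
        np.array([1, 0, 1, 0, 0, 1], dtype=bool), branch_offset=12.0,
    )
    s2 = SpineSegment(
        "c1", "s2", np.array([0.0, 3.0, 6.0, 9.0]),
        np.array([0, 1, 1, 0], dtype=bool), branch_offset=30.0,
    )
    return SpineDataset([s1, s2])
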