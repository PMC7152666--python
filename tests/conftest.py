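import numpy as np
import pytest

from gazegroup.io import Dataset, FixationRecord, Scanpath
from gazegroup.metrics import compute_metric_table
from gazegroup.simulate import default_recovery_benchmark


def make_scanpath(pid, sid, rows):
    """rows: list of (x, y, start, duration)."""
    fixes = [FixationRecord(pid, sid, x, y, t, d) for x, y, t, d in rows]
    return Scanpath(pid, sid, fixes)


@pytest.fixture
def toy_scanpath():
    """3-4-5-triangle scanpath with closed-form metric values."""
    return make_scanpath("P1", "S1", [(0, 0, 0, 100), (3, 4, 150, 200), (6, 8, 400, 300)])


@pytest.fixture
def focal_ambient_dataset():
    """Two scanpaths: A focal (long fixations, short saccades), B ambient."""
    ds = Dataset()
    ds.add(make_scanpath("A", "S1", [(0, 0, 0, 400), (10, 0, 450, 400), (20, 0, 900, 400)]))
    ds.add(make_scanpath("B", "S1", [(0, 0, 0, 100), (400, 0, 150, 100), (800, 0, 300, 100)]))
    return ds


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark (seed 1): dataset, truth labels, metric table."""
    ds, truth = default_recovery_benchmark(1)
    table = compute_metric_table(ds)
    return ds, truth, table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
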