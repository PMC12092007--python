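import numpy as np
import pandas as pd
import pytest

from duster.pickio import PickSet, RecenteredPickSet


def random_pickset(rng, n, run_id=1, n_micrographs=3, pixel_size=1.0,
                   size=1024.0):
    """Random but valid PickSet for round-trip/partition tests."""
    df = pd.DataFrame({
        "pick_id": [f"{run_id}:{i}" for i in range(n)],
        "micrograph_id": [f"mic_{rng.integers(n_micrographs):03d}"
                          for _ in range(n)],
        "run_id": run_id,
        "x": rng.uniform(0, size, n),
        "y": rng.uniform(0, size, n),
    })
    return PickSet(df, pixel_size)


def recentered_from_points(points, run, pixel_size=1.0, mic="mic_000",
                           probs=None):
    """RecenteredPickSet with given (x, y) refined points on one
    micrograph; shifts zero, one class."""
    n = len(points)
    df = pd.DataFrame({
        "pick_id": [f"{run}:{i}" for i in range(n)],
        "micrograph_id": mic,
        "x_ref": [p[0] for p in points],
        "y_ref": [p[1] for p in points],
        "dx": 0.0,
        "dy": 0.0,
        "class_id": 0,
        "class_prob": probs if probs is not None else 1.0,
    })
    return RecenteredPickSet(df, pixel_size, source_run=run)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
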