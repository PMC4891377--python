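import numpy as np
import pytest

from unbiased import RunSeries, Session, DesignSpec, generate_session, preset


def voxel_run(series, run_id=0, tr=2.5):
    """A RunSeries with a single voxel holding the given time course."""
    arr = np.asarray(series, dtype=float).reshape(1, 1, 1, -1)
    return RunSeries(data=arr, tr=tr, run_id=run_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20160310)


@pytest.fixture(scope="session")
def two_run_session():
    return generate_session(preset("two_run", seed=1))


@pytest.fixture(scope="session")
def motor_session():
    """10-run motor-design session with one strong canonical region."""
    return generate_session(preset("motor_basic", seed=42))


def tiny_session(n_runs=3, grid=(4, 4, 2), T=16, tr=2.5, seed=0, scale=1.0):
    """Small unstructured random session for structural tests."""
    g = np.random.default_rng(seed)
    design = DesignSpec(block_onsets=(10.0,), block_durations=(10.0,),
                        total_duration=T * tr, label="tiny")
    runs = [RunSeries(data=1000 + scale * g.standard_normal(grid + (T,)),
                      tr=tr, run_id=i) for i in range(n_runs)]
    return Session(runs=runs, mask=np.ones(grid, bool), design=design)
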