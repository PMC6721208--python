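import numpy as np
import pytest

from cladetime.preprocess import Cohort
from cladetime.pool import PoolParams, build_pool


def make_cohort(n_subjects=8, n_times=12, taxa=("A", "B", "C", "D", "E"),
                seed=0, t_end=10.0, signal=0.0):
    """Small programmatic cohort: flat taxonomy, dense regular sampling.

    ``signal`` shifts taxon 0 upward for odd-indexed (case) subjects.
    """
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, t_end, n_times)
    subjects = [f"s{i}" for i in range(n_subjects)]
    y = (np.arange(n_subjects) % 2).astype(int)
    abundance = {}
    tdict = {}
    for i, s in enumerate(subjects):
        base = 0.2 + 0.05 * rng.normal(size=(len(taxa), n_times))
        base[0] += signal * y[i]
        abundance[s] = np.clip(base, 1e-3, None)
        tdict[s] = times.copy()
    return Cohort(
        subjects=subjects, y=y, times=tdict, abundance=abundance,
        taxa=list(taxa), parent={t: None for t in taxa},
        t_start=0.0, t_end=t_end,
        label_mapping={"control": 0, "case": 1},
    )


@pytest.fixture
def toy_cohort():
    return make_cohort()


@pytest.fixture
def toy_pool(toy_cohort):
    return build_pool(toy_cohort, PoolParams(n_w=4, n_theta=40))


@pytest.fixture
def tiny_pool(toy_cohort):
    """Six-detector pool for exhaustively enumerable problems."""
    full = build_pool(toy_cohort, PoolParams(n_w=2, n_theta=3))
    return full.subset(np.linspace(0, full.n_detectors - 1, 6).astype(int))
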