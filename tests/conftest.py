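"""Shared fixtures.

The heavy objects — the six-attractor library, its classifier, the indexed
memory ensemble and the index-free memory — are session-scoped and shared
between the unit tests and the experiment-level tests so each is built once.
"""

import numpy as np
import pytest

from rcmem.classify import train_classifier
from rcmem.io import six_attractor_library
from rcmem.memory import ReservoirMemory, train_indexfree


@pytest.fixture(scope="session")
def six_lib():
    return six_attractor_library(seed=0)


@pytest.fixture(scope="session")
def six_clf(six_lib):
    return train_classifier(six_lib, seed=5)


@pytest.fixture(scope="session")
def six_mem(six_lib):
    """One reference indexed memory over the six attractors."""
    return ReservoirMemory(N=1000, seed=1).fit(six_lib)


@pytest.fixture(scope="session")
def six_mem_ensemble(six_lib):
    """Five indexed memories with independent reservoir seeds."""
    return [ReservoirMemory(N=1000, seed=s).fit(six_lib) for s in range(1, 6)]


@pytest.fixture(scope="session")
def indexfree_mem(six_lib):
    """The index-free (content-addressable) six-attractor reference model."""
    return train_indexfree(six_lib, N=1000, seed=2)


@pytest.fixture(scope="session")
def lorenz_fine():
    """Long Lorenz trajectory at the integration step (for climate metrics)."""
    from rcmem.dynamics import SystemSpec, integrate_system

    spec = SystemSpec("lorenz", integrate_dt=0.01, sample_every=1, transient_steps=2000)
    return integrate_system(spec, 150_000, seed=1)


@pytest.fixture(scope="session")
def lorenz_coarse():
    """Lorenz at dt = 0.1, subsampled scale used for dimension estimates."""
    from rcmem.dynamics import SystemSpec, integrate_system

    spec = SystemSpec("lorenz", integrate_dt=0.01, sample_every=10, transient_steps=1000)
    return integrate_system(spec, 50_000, seed=2)
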