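"""Shared simulation runs: the expensive colonies are grown once per session."""

import numpy as np
import pytest

from colonypress import engine

#: Seeds used by the multi-seed statistical checks.
SEEDS = tuple(range(10))


@pytest.fixture(scope="session")
def vertical_runs():
    """Ten vertical-section colonies grown to ~400 cells."""
    return [engine.run(engine.vertical_section_config(seed=s, max_cells=400))
            for s in SEEDS]


@pytest.fixture(scope="session")
def topdown_runs():
    """Ten standard-surface top-down colonies grown to ~600 cells."""
    return [engine.run(engine.top_down_config(seed=s, max_cells=600))
            for s in SEEDS]


@pytest.fixture(scope="session")
def soft_runs():
    """Ten soft-surface (large solver budget) top-down colonies, ~600 cells."""
    return [engine.run(engine.top_down_config(seed=s, max_cells=600,
                                              surface="soft"))
            for s in SEEDS]


@pytest.fixture(scope="session")
def stiff_runs():
    """Ten stiff-surface (small solver budget) top-down colonies, ~600 cells."""
    return [engine.run(engine.top_down_config(seed=s, max_cells=600,
                                              surface="stiff"))
            for s in SEEDS]


@pytest.fixture(scope="session")
def twocolony_runs():
    """Ten two-colony merge runs at the default separation."""
    return [engine.run_two_colony(engine.two_colony_config(seed=s))
            for s in SEEDS]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
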