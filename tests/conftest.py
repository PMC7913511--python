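"""Shared fixtures: the worked-example heifer series and its fitted model."""

import numpy as np
import pytest

import calvehmm as ch

# Hourly posture-change counts for the reference heifer, hours -72..-1,
# frozen independently of the packaged CSV so the fixture file is checked
# against a second copy of the published record.
COW1_COUNTS = (
    2, 2, 5, 6, 1, 2, 1, 0, 0, 2, 2, 2, 2, 1, 2, 2, 1, 0, 0, 0, 1, 1, 2, 1,
    2, 4, 2, 3, 1, 2, 1, 0, 1, 2, 2, 1, 4, 1, 2, 1, 0, 0, 0, 1, 4, 2, 3, 0,
    3, 3, 4, 2, 4, 2, 2, 0, 0, 0, 0, 4, 2, 0, 1, 1, 2, 2, 2, 6, 2, 2, 5, 13,
)

# Published hourly activity-level labels for the same record.
COW1_HOURLY_LEVELS = (
    "MMHHLMLLLMMMMLMMLLLLLLML"
    "MHMMLMLLLMMLHLMLLLLLHMML"
    "MMHMHMMLLLLHMLLLMMMHMMHH"
)

# Published 3-hour activity labels (intervals 1..24, earliest first).
COW1_WINDOWED_LEVELS = "LLLLLLLLLLLLLLLLMLLLLLMH"


@pytest.fixture(scope="session")
def cow1():
    return ch.load_example_cow()


@pytest.fixture(scope="session")
def cow1_stats(cow1):
    return ch.summary_stats(cow1.counts)


@pytest.fixture(scope="session")
def cow1_hourly(cow1, cow1_stats):
    return ch.hourly_levels(cow1, cow1_stats)


@pytest.fixture(scope="session")
def cow1_windowed(cow1):
    return ch.discretize(cow1, window=3)


@pytest.fixture(scope="session")
def fitted_params(cow1_hourly):
    """The reference model fitted from the worked-example heifer."""
    return ch.build_hmm(cow1_hourly, ch.SegmentSpec(60, 12))


def random_hmm(rng: np.random.Generator) -> ch.HMMParams:
    """Random valid 2-state/3-symbol HMM for property tests."""
    def rows(shape):
        x = rng.dirichlet(np.ones(shape[1]), size=shape[0])
        return x
    return ch.HMMParams(A=rows((2, 2)), B=rows((2, 3)), Pi=rng.dirichlet(np.ones(2)))
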