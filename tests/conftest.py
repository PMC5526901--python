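"""Shared fixtures: synthetic samples are generated once per session."""

import numpy as np
import pytest

from cytogate.io import ChannelInfo, EventTable
from cytogate.simulate import preset_populations, preset_profile, simulate_donor


@pytest.fixture(scope="session")
def spikein1_sample() -> EventTable:
    """Undiluted spike-in positive donor, 2e5 events (1.7% multimer+ of
    live single lymphocytes)."""
    return simulate_donor(
        preset_populations("spikein1-positive"),
        preset_profile("spikein1-positive"),
        200_000,
        seed=20_260_924,
    )


@pytest.fixture(scope="session")
def high_freq_sample() -> EventTable:
    """High-frequency proficiency donor (5.33% multimer+ of CD8), 1e5 events."""
    return simulate_donor(
        preset_populations("519-EBV"), preset_profile("519-EBV"), 100_000, seed=99
    )


def two_channel_table(values: np.ndarray) -> EventTable:
    """Wrap a plain (n, 2) array as a CD8 x multimer event table."""
    return EventTable(
        values=np.asarray(values, dtype=float),
        channels=[
            ChannelInfo("X", role="CD8"),
            ChannelInfo("Y", role="multimer-PE"),
        ],
    )
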