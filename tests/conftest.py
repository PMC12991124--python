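import numpy as np
import pytest
from hypothesis import settings

from cysreact.datamodel import ChannelAssignment, PeptideQuantRecord, PlexLayout, ProteinDatabase

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def two_channel_layout():
    """Minimal single-plex layout: one reference channel, one D8C channel."""
    return PlexLayout(
        plex_id="p1",
        channels=[
            ChannelAssignment("126", "D2", 1),
            ChannelAssignment("127N", "D8C", 1),
        ],
    )


@pytest.fixture
def ten_channel_layouts():
    """Two 10-plex layouts: five conditions x two channels, reference D2."""
    labels = ["126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131"]
    conditions = ["D2", "D4A", "D4C", "D8A", "D8C"]
    layouts = []
    for plex in ("p1", "p2"):
        channels = []
        k = 0
        for cond in conditions:
            for rep in (1, 2):
                channels.append(ChannelAssignment(labels[k], cond, rep))
                k += 1
        layouts.append(PlexLayout(plex_id=plex, channels=channels))
    return layouts


@pytest.fixture
def tiny_database():
    return ProteinDatabase({"P1": "MKCATRCK", "P2": "MAAAKCCDEFGHIKAAAR"})


def make_record(accession, sequence, offsets, intensities, plex="p1"):
    return PeptideQuantRecord(
        protein_accession=accession,
        base_sequence=sequence,
        modified_offsets=tuple(offsets),
        intensities=dict(intensities),
        plex_id=plex,
    ).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
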