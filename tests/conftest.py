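"""Shared fixtures: small planted loci and libraries built once per session."""

from __future__ import annotations

import pytest

from immloci.annotate import Cassette
from immloci.simulate import (
    DefectRates,
    JunctionModel,
    LocusSpec,
    make_segment_library,
    plant_locus,
    simulate_transcripts,
)


@pytest.fixture(scope="session")
def trb_spec():
    return LocusSpec(locus="TRB", n_v=10, n_j=6, n_c=1)


@pytest.fixture(scope="session")
def trb_locus(trb_spec):
    library = make_segment_library(trb_spec, seed=1)
    chromosome, truth = plant_locus(library, trb_spec, seed=2)
    return library, chromosome, truth


@pytest.fixture(scope="session")
def trb_cassette_locus():
    cassette = Cassette(elements=(("D", (1, 1, 1)), ("J", (6, 7, 6)), ("C", (1, 1, 1))))
    spec = LocusSpec(locus="TRB", cassette=cassette, n_v=4)
    library = make_segment_library(spec, seed=3)
    chromosome, truth = plant_locus(library, spec, seed=4)
    return spec, library, chromosome, truth


@pytest.fixture(scope="session")
def igh_repertoire():
    spec = LocusSpec(locus="IGH", n_v=10, n_d=5, n_j=4, n_c=2)
    library = make_segment_library(spec, seed=9)
    weights = {
        "V": {f"IGHV{i + 1}": 0.1 for i in range(10)},
        "J": {f"IGHJ{i + 1}": 0.25 for i in range(4)},
    }
    transcripts, truth = simulate_transcripts(
        library, weights, JunctionModel(), n=300, seed=9
    )
    return library, weights, transcripts, truth
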