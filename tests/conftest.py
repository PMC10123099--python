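"""Shared fixtures: one synthetic data set generated per test session."""

from __future__ import annotations

import json

import pytest

from splicesuite.annotation import GenomeSequence, build_junction_index, read_bed12
from splicesuite.fixtures import FixtureSpec, generate, generate_compare_dir
from splicesuite.rmats_io import (
    ASType,
    SignificanceFilter,
    Sign,
    filter_significant,
    read_rmats,
)

SEED = 42


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    generate(FixtureSpec(seed=SEED), out)
    generate_compare_dir(out / "compare", seed=SEED)
    return out


@pytest.fixture(scope="session")
def truth(fixture_dir):
    with open(fixture_dir / "truth.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def compare_truth(fixture_dir):
    with open(fixture_dir / "compare" / "compare_truth.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def se_events(fixture_dir):
    return read_rmats(fixture_dir / "fixture_SE.MATS.JCEC.txt", ASType.SE)


@pytest.fixture(scope="session")
def ri_events(fixture_dir):
    return read_rmats(fixture_dir / "fixture_RI.MATS.JCEC.txt", ASType.RI)


@pytest.fixture(scope="session")
def sig_neg(se_events):
    return filter_significant(se_events, SignificanceFilter(0.0005, Sign.NEGATIVE))


@pytest.fixture(scope="session")
def sig_pos(se_events):
    return filter_significant(se_events, SignificanceFilter(0.0005, Sign.POSITIVE))


@pytest.fixture(scope="session")
def transcripts(fixture_dir):
    return read_bed12(fixture_dir / "annotation.bed")


@pytest.fixture(scope="session")
def junction_index(transcripts):
    return build_junction_index(transcripts)


@pytest.fixture(scope="session")
def genome(fixture_dir):
    return GenomeSequence(fixture_dir / "genome.fa")
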