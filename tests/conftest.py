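"""Shared fixtures: one generated toy study per session plus a pipeline run."""
from __future__ import annotations

import random

import pytest

from neopept.fixtures import FixtureSpec, make_fixture
from neopept.pipeline import config_for_fixture, run_pipeline
from neopept.transcript import open_genome


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    return make_fixture(FixtureSpec(seed=17), tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def fixture_config(fixture_set):
    return config_for_fixture(fixture_set, seed=17)


@pytest.fixture(scope="session")
def pipeline_result(fixture_config):
    return run_pipeline(fixture_config)


@pytest.fixture(scope="session")
def fixture_models(fixture_set):
    from neopept.formats import read_gtf

    return read_gtf(fixture_set.path("gtf"))


@pytest.fixture(scope="session")
def fixture_genome(fixture_set):
    return open_genome(fixture_set.path("fasta"))


@pytest.fixture()
def rng():
    return random.Random(20260929)
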