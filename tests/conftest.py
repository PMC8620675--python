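"""Shared fixtures: a small planted-repeat study for unit-level checks and
one full-size hierarchical study (built once per session) for the
end-to-end recovery and structure tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

# property tests must be reproducible run to run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from repeatome.kchain import DiscoveryParams, discover
from repeatome.quantify import build_matrix, map_reads
from repeatome.simulate import RepeatFamilySpec, StudySpec, make_study

STUDY_SEED = 1


def hierarchical_study_spec(seed: int = STUDY_SEED) -> StudySpec:
    """The package's reference synthetic study: 4 species x 3 replicates,
    100-kb backgrounds, read length 100 at 20x with 0.5% sequencing error;
    three 120-bp nuclear repeat families shared hierarchically ({A,B},
    {A,B,C}, {D}-private; every family at 300 copies in at least one
    species) plus one chloroplast-like contaminant family planted equally
    in all species."""
    return StudySpec(
        species=("speciesA", "speciesB", "speciesC", "speciesD"),
        replicates=3,
        background_length=100_000,
        families=(
            RepeatFamilySpec("famAB", 120, {"speciesA": 300, "speciesB": 150}),
            RepeatFamilySpec("famABC", 120, {"speciesA": 50, "speciesB": 100, "speciesC": 300}),
            RepeatFamilySpec("famD", 120, {"speciesD": 300}),
            RepeatFamilySpec("cp", 120, {s: 50 for s in ("speciesA", "speciesB", "speciesC", "speciesD")}),
        ),
        read_length=100,
        depth=20.0,
        error_rate=0.005,
        seed=seed,
    )


@pytest.fixture(scope="session")
def study():
    return make_study(hierarchical_study_spec())


@pytest.fixture(scope="session")
def pooled_reads(study):
    return [r for e in study.manifest.entries for r in study.reads[e.sample_id]]


@pytest.fixture(scope="session")
def kchains(pooled_reads):
    return discover(pooled_reads, DiscoveryParams(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def truth_raw_matrix(study):
    """Raw abundance of every sample quantified against the planted family
    consensi (the ground-truth references)."""
    refs = sorted(study.consensi.items())
    profiles = {
        sid: map_reads(reads, refs, seed_k=12, min_identity=0.9)
        for sid, reads in study.reads.items()
    }
    return build_matrix(study.manifest, refs, profiles, statistic="median")


@pytest.fixture(scope="session")
def tiny_study():
    """A two-species, one-family study small enough for fast unit tests."""
    spec = StudySpec(
        species=("left", "right"),
        replicates=2,
        background_length=20_000,
        families=(RepeatFamilySpec("fam1", 120, {"left": 80, "right": 20}),),
        read_length=100,
        depth=8.0,
        error_rate=0.005,
        seed=3,
    )
    return make_study(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
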