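import dataclasses

import pytest

from bacmap import ScoreParams, initial_build
from bacmap import simdata as sd


@pytest.fixture(scope="session")
def default_params():
    return ScoreParams()


@pytest.fixture(scope="session")
def small_noiseless_sim():
    """A 600 kb single-chromosome region tiled by 60 noiseless clones,
    with ground truth. Session-scoped: read-only in tests."""
    genome = sd.simulate_genome(600_000, 1, n_markers=0, seed=3)
    spec = dataclasses.replace(sd.AF_BB, n_clones=60, empty_rate=0.0)
    clones = sd.simulate_library(genome, spec, seed=4)
    profiles = sd.simulate_fingerprints(clones, genome, sd.NOISELESS)
    return genome, clones, profiles


@pytest.fixture(scope="session")
def multi_lg_sim():
    """3 Mb, 7 linkage groups, 300 noiseless clones from both libraries."""
    genome = sd.simulate_genome(3_000_000, 7, n_markers=0, seed=11)
    clones = []
    for k, spec in enumerate((sd.AF_BB, sd.AF_BC)):
        spec = dataclasses.replace(
            spec, n_clones=150, empty_rate=0.0, fingerprint_fail_rate=0.0
        )
        clones += sd.simulate_library(genome, spec, seed=12 + k)
    profiles = sd.simulate_fingerprints(clones, genome, sd.NOISELESS)
    return genome, clones, profiles


@pytest.fixture(scope="session")
def small_build(small_noiseless_sim, default_params):
    _genome, _clones, profiles = small_noiseless_sim
    build, table = initial_build(profiles, default_params)
    return build, table, profiles
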