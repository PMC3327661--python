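"""Shared fixtures: one small simulated experiment reused across the suite."""

from __future__ import annotations

from pathlib import Path

import pytest

from avimir.annotate import annotate_library
from avimir.preprocess import build_library
from avimir.quantify import build_count_table
from avimir.simdata import default_spec, make_reference_set, simulate_libraries

SMALL_SEED = 11
SMALL_DEPTH = 8000


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """depth-8000 six-library simulation: spec, reference set, truth, FASTQ dir."""
    out = tmp_path_factory.mktemp("small_sim")
    spec = default_spec(depth=SMALL_DEPTH)
    rs, truth = make_reference_set(spec, SMALL_SEED)
    simulate_libraries(spec, rs, truth, SMALL_SEED, out)
    return spec, rs, truth, out


@pytest.fixture(scope="session")
def small_libraries(small_sim):
    spec, rs, truth, out = small_sim
    return [
        build_library(
            Path(out) / f"{ls.id}.fastq", ls.id, ls.species, ls.stage, spec.adapter
        )
        for ls in spec.libraries
    ]


@pytest.fixture(scope="session")
def small_annotated(small_sim, small_libraries):
    _, rs, _, _ = small_sim
    return [annotate_library(lib, rs) for lib in small_libraries]


@pytest.fixture(scope="session")
def small_count_table(small_annotated):
    return build_count_table(small_annotated)


@pytest.fixture(scope="session")
def small_lib_meta(small_libraries):
    return {lib.id: (lib.species, lib.stage) for lib in small_libraries}
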