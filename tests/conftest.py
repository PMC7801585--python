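"""Shared fixtures: a small synthetic dataset for unit/integration tests
and the full-scale default dataset for end-to-end recovery checks."""

from __future__ import annotations

import pytest

from venomlgt.formats_io import load_config
from venomlgt.pipeline import run_discovery
from venomlgt.synthetic_data import SimConfig, generate_dataset

# a scaled-down dataset for fast integration tests: same structure as the
# default, smaller genome and fewer ortholog pairs
SMALL_KW = dict(
    genome_length=600_000,
    n_planted_loci=6,
    island_size=20_000,
    omega_grid=((0.15, 0.3, 130), (0.5, 0.3, 15), (0.01, 0.3, 45),
                (0.15, 3.0, 4)),
    n_specific_a=60,
    n_specific_b=60,
    n_lgt_trees=6,
    n_vertical_trees=6,
)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("small_ds")
    truth = generate_dataset(SimConfig(seed=7, **SMALL_KW), out)
    return out, truth


@pytest.fixture(scope="session")
def small_report(small_dataset):
    """Discovery run on the small dataset, homology search off (the search
    has its own unit and end-to-end coverage)."""
    out, _truth = small_dataset
    return run_discovery(load_config(run_homology_search=False), out)


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The full-scale default synthetic dataset (the study conditions)."""
    out = tmp_path_factory.mktemp("default_ds")
    truth = generate_dataset(SimConfig(seed=1), out)
    return out, truth


@pytest.fixture(scope="session")
def default_report(default_dataset):
    """Full discovery run (homology search included) on the default
    dataset."""
    out, _truth = default_dataset
    return run_discovery(load_config(), out)
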