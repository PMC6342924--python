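"""Shared fixtures: a small planted genome and a small full-pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from pirnascape.pipeline import PipelineConfig, run_pipeline
from pirnascape.simulate import (GenomeConfig, default_study_profiles,
                                 generate_genome, simulate_library)


@pytest.fixture(scope="session")
def small_genome():
    """Planted genome small enough for brute-force cross-checks."""
    return generate_genome(GenomeConfig(
        n_scaffolds=4, scaffold_length=25_000, n_clusters=12,
        cluster_length_range=(400, 1500), frac_tandem=0.34,
        tandem_copy_range=(3, 4), seed=11))


@pytest.fixture(scope="session")
def small_library(small_genome):
    """One somatic library simulated from the small genome."""
    profile = default_study_profiles(n_reads=8_000, seed=5)[0]
    reads, truth = simulate_library(small_genome, profile)
    return profile, reads, truth


@pytest.fixture(scope="session")
def small_run():
    """A complete but scaled-down pipeline run with planted truth."""
    cfg = PipelineConfig(
        seed=13, n_reads_per_library=8_000,
        genome=GenomeConfig(n_scaffolds=6, scaffold_length=30_000,
                            n_clusters=20, seed=0),
        write_intermediate=False)
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
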