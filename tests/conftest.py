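"""Shared fixtures: a small synthetic bundle and a pipeline run on it.

Session-scoped so the simulation and the end-to-end run are paid once.
"""

from __future__ import annotations

import numpy as np
import pytest
from intervaltree import IntervalTree

from srnaome import annotation as ann
from srnaome import pipeline as pl
from srnaome.core import CollapseStats
from srnaome.simulate import (SimulationConfig, build_genome,
                              simulate_degradome, simulate_srna_libraries)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=7, genome_length=300_000, n_mirnas=8, n_phas_loci=3,
        library_depth=50_000, noise_pool_size=300,
        contaminant_pool_size=150)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return build_genome(small_config)


@pytest.fixture(scope="session")
def small_libraries(small_bundle):
    counts, table = simulate_srna_libraries(small_bundle)
    return counts


@pytest.fixture(scope="session")
def small_degradome(small_bundle):
    return simulate_degradome(small_bundle, peak_height=50,
                              noise_per_position=1)


def run_bundle(bundle, libraries, degradome_counts, n_shuffles=50, seed=1,
               thresholds=None):
    """Run the in-memory pipeline on a simulated bundle."""
    ncrna: dict[str, IntervalTree] = {}
    for chrom, s, e, _strand, nctype in bundle.ncrna:
        ncrna.setdefault(chrom, IntervalTree())[s:e] = nctype
    te: dict[str, IntervalTree] = {}
    for chrom, s, e, _strand in bundle.te:
        te.setdefault(chrom, IntervalTree())[s:e] = "TE"
    annot = ann.Annotation.from_genes(bundle.genes)
    library_counts = {
        lib: (counts, CollapseStats(lib, sum(counts.values())))
        for lib, counts in libraries.items()}
    return pl.run_in_memory(
        genome=bundle.genome, library_counts=library_counts,
        catalog=bundle.catalog, ncrna=ncrna, te=te, annotation=annot,
        transcripts=bundle.transcripts,
        expressed_transcripts=bundle.expressed_transcripts,
        degradome_counts=degradome_counts,
        contaminant=bundle.contaminant_genome, seed=seed,
        n_shuffles=n_shuffles, thresholds=thresholds)


@pytest.fixture(scope="session")
def small_result(small_bundle, small_libraries, small_degradome):
    return run_bundle(small_bundle, small_libraries, small_degradome)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
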