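"""Shared fixtures: simulated pangenomes at two scales plus the PSSM library.

The session-scoped "study" pangenome is the package's standard test
condition (12 genotypes, 8 families, ~0.5 Mb per genotype, ~1% background
divergence) and is reused by the planted-recovery and acceptance tests; the
small pangenome keeps per-module tests fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from panfam.align import KmerIndex
from panfam.domains import build_pssm, calibrate_null
from panfam.pangene import SearchParams, validate_gene
from panfam.simpan import SimConfig, make_domain_library, sample_instance, simulate_pangenome

STUDY_SEED = 11


@pytest.fixture(scope="session")
def domain_library():
    return make_domain_library(seed=1)


@pytest.fixture(scope="session")
def small_pangenome():
    return simulate_pangenome(
        SimConfig(n_genotypes=4, n_families=5, genome_length=80_000, seed=3)
    )


@pytest.fixture(scope="session")
def study_pangenome():
    return simulate_pangenome(SimConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def study_validation(study_pangenome):
    indexes = {
        g.genotype_id: KmerIndex(g.assembly, 15)
        for g in study_pangenome.genotypes
    }
    params = SearchParams()
    return {
        gene.family_id: validate_gene(gene.family_id, gene.gene_seq(),
                                      indexes, params)
        for gene in study_pangenome.founder.genes
    }


@pytest.fixture(scope="session")
def pssm_library(study_pangenome):
    """PSSMs built from the simulation's domain templates, each with its
    calibrated null."""
    rng = np.random.default_rng([STUDY_SEED, 11])
    pssms, calibrations = [], {}
    for i, template in enumerate(study_pangenome.founder.templates):
        pssm = build_pssm(
            [sample_instance(template, rng) for _ in range(30)],
            pseudocount=1.0, label=template.label,
        )
        pssms.append(pssm)
        calibrations[template.label] = calibrate_null(
            pssm, decoy_length_total=100_000, n_samples=200,
            seed=STUDY_SEED + 23 + i, query_windows=10_000,
        )
    return pssms, calibrations
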