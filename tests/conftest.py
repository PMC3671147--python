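"""Shared fixtures: one small heterozygous amplicon world reused across
module tests (session-scoped: simulation and pipeline run once)."""

from __future__ import annotations

import numpy as np
import pytest

import hlaphase as hp


@pytest.fixture(scope="session")
def het_world():
    """Error-free heterozygous sample on a 2 kb toy amplicon."""
    cfg = hp.SimulationConfig(gene_length=2000, n_snv=20, n_indel=2,
                              n_pairs=600, fragment_min=500, fragment_max=1600,
                              fragment_mean=900, fragment_sd=200, seed=1)
    ref = hp.simulate_reference(cfg, name="TOYA")
    truth = hp.simulate_haplotype_pair(ref, cfg)
    pairs = hp.simulate_read_pairs(truth, cfg)
    return cfg, ref, truth, pairs


@pytest.fixture(scope="session")
def het_mapped(het_world):
    """Internally aligned pairs of the het world."""
    _, ref, _, pairs = het_world
    aligner = hp.ReadAligner([ref])
    return [aligner.align_pair(p) for p in pairs]


@pytest.fixture(scope="session")
def het_result(het_world):
    _, ref, _, pairs = het_world
    return hp.run_gene_tagging(pairs, ref, hp.PipelineConfig(), sample="S1")


@pytest.fixture(scope="session")
def toy_db():
    """Two-gene toy allele database (24 genomic + 6 cDNA-only entries)."""
    refA = hp.simulate_reference(hp.SimulationConfig(gene_length=1200, seed=11),
                                 name="TOYA")
    refB = hp.simulate_reference(hp.SimulationConfig(gene_length=1500, seed=12),
                                 name="TOYB")
    db = hp.simulate_allele_database([refA, refB], n_alleles_per_gene=12, seed=5)
    return refA, refB, db


def truth_trimmed(ref, truth, margin=5):
    """Truth haplotype sequences over the primer-trimmed interval."""
    lo, hi = ref.trimmed_interval
    lo, hi = lo + margin, hi - margin
    th1 = truth.hap1_seq[lo:hi]
    th2 = truth.hap2_seq[truth.layout2.ref_to_hap(lo):truth.layout2.ref_to_hap(hi)]
    return th1, th2


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
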