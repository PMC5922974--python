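"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from tdnaseq.models import GeneModel
from tdnaseq.simulate import (
    SimConfig,
    make_genome_and_genes,
    make_true_pool,
    make_tnseq_reads,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(seed=1, n_insertions=400, n_genes=40, genome_length=120_000)


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return make_genome_and_genes(small_cfg)


@pytest.fixture(scope="session")
def small_pool_df(small_cfg, small_truth):
    return make_true_pool(small_cfg, small_truth)


@pytest.fixture(scope="session")
def small_tnseq(small_cfg, small_truth, small_pool_df):
    return make_tnseq_reads(small_pool_df, small_truth, small_cfg)


@pytest.fixture
def plus_gene() -> GeneModel:
    """One-exon-free toy gene on +: tx 100-400, CDS 150-390."""
    return GeneModel(
        gene_id="gA",
        scaffold="s1",
        strand="+",
        tx_start=100,
        tx_end=400,
        cds_start=150,
        cds_end=390,
        exons=[(100, 400)],
        utr5=[(100, 150)],
        utr3=[(390, 400)],
    )


@pytest.fixture
def minus_gene() -> GeneModel:
    return GeneModel(
        gene_id="gB",
        scaffold="s1",
        strand="-",
        tx_start=100,
        tx_end=400,
        cds_start=150,
        cds_end=390,
        exons=[(100, 400)],
        utr5=[(390, 400)],
        utr3=[(100, 150)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
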