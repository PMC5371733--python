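import numpy as np
import pandas as pd
import pytest

from nascent.simgen import SimConfig, simulate_counts, simulate_world


@pytest.fixture(scope="session")
def small_world():
    return simulate_world(SimConfig.small(), seed=1)


@pytest.fixture(scope="session")
def small_counts(small_world):
    return simulate_counts(small_world, seed=2)


@pytest.fixture(scope="session")
def clean_counts(small_world):
    """Noise-free, bleed-free observations of the small world."""
    return simulate_counts(small_world, seed=2, noise=False, antisense_c=0.0)


@pytest.fixture()
def toy_genes():
    genes = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [1000, 20000, 40000],
            "end": [11000, 30000, 41000],
            "strand": ["+", "-", "+"],
            "biotype": ["protein_coding", "lincRNA", "protein_coding"],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    exons = pd.DataFrame(
        {
            "gene_id": ["gA", "gA", "gB", "gC"],
            "transcript_id": ["gA.t1", "gA.t1", "gB.t1", "gC.t1"],
            "chrom": ["chr1"] * 4,
            "start": [1000, 6000, 20000, 40000],
            "end": [3000, 11000, 30000, 41000],
            "strand": ["+", "+", "-", "+"],
        }
    )
    return genes, exons
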