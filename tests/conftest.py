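import numpy as np
import pandas as pd
import pytest

from genecross import synth


@pytest.fixture(scope="session")
def small_cross():
    """An RI cross with a strong planted QTL mid-chromosome 1."""
    spec = synth.CrossSimSpec(qtl_marker=15, qtl_effect=2.0, seed=11)
    return synth.gen_cross(spec)


@pytest.fixture(scope="session")
def small_gwas():
    """LD-blocked GWAS with a planted causal gene, plus its gene table."""
    genes = synth.gen_genes(20, 2, 4_000_000, prefix="HG")
    spec = synth.GwasSimSpec(
        n_individuals=1000, n_blocks=20, snps_per_block=8,
        causal_gene="HG0005", causal_beta=0.5, seed=7,
    )
    snps, panel, truth = synth.gen_gwas(spec, genes)
    return genes, snps, panel, truth


@pytest.fixture(scope="session")
def small_expression():
    """Expression matrix with an 8-gene planted module; focal gene has 6+11 probes."""
    module = frozenset({"G0003", "G0010", "G0020", "G0030", "G0040", "G0050", "G0060", "G0070"})
    spec = synth.ExprSimSpec(
        n_strains=70, n_genes=80, probes_per_gene=(2, 4),
        module_genes=module, module_r=0.85, n_noise_probes=11, seed=5,
    )
    expr, probes = synth.gen_expression(spec)
    return expr, probes, sorted(module)


@pytest.fixture
def toy_markers():
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
            "pos_bp": [100, 300, 500, 100, 200],
            "marker_id": ["m1", "m2", "m3", "m4", "m5"],
            "p": [0.02, 0.04, 0.10, 0.007, 0.5],
        }
    )


def make_genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start_bp", "end_bp"])


@pytest.fixture
def rng():
    return np.random.default_rng(123)
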