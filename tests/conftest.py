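import numpy as np
import pandas as pd
import pytest

from pathgxe import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    return sim.SimulationConfig(
        n_genes=20,
        n_pathways_per_library={"LIB": 4},
        genes_per_pathway=(3, 6),
        snps_per_gene=(2, 5),
        causal_pathways=("LIB_0001",),
        beta_gxe=0.4,
        n_cases=300,
        n_controls=300,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Annotation + libraries + cohort, shared across tests (read-only)."""
    genes, snps = sim.make_annotation(small_config)
    libraries = sim.make_gene_sets(small_config, genes["gene_id"])
    cohort = sim.simulate_cohort(small_config, snps, libraries)
    return {
        "config": small_config,
        "genes": genes,
        "snps": snps,
        "libraries": libraries,
        "cohort": cohort,
    }


@pytest.fixture()
def toy_stats():
    """Hand-built summary statistics for four SNPs on one chromosome."""
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "pos": [100, 200, 300, 400],
            "snp_id": ["s1", "s2", "s3", "s4"],
            "exposure": ["bmi"] * 4,
            "beta": [0.5, -0.1, 0.0, 0.3],
            "se": [0.1, 0.1, 0.2, 0.15],
            "p": [1e-6, 0.32, 1.0, 0.045],
        }
    )
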