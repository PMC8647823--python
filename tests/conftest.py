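import numpy as np
import pandas as pd
import pytest

from rhizoepi.config import CopyPlan, GenePlan, SimulationConfig, SrnaModel
from rhizoepi.synthetic import generate_genome


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A scaled-down simulation for fast unit tests: ~0.3 Mb, ~90 TE copies,
    ~90 genes, ~30 sRNA loci. Keeps every structural feature of the default
    study conditions (two divergence waves, MULE-paired Class C genes, mito
    contig) at a fraction of the size."""
    copy_plan = {
        "MULE1": CopyPlan(n_copies=20, young_fraction=0.6),
        "CMC1": CopyPlan(n_copies=10),
        "hAT1": CopyPlan(n_copies=10),
        "TcMar1": CopyPlan(n_copies=10),
        "Gypsy1": CopyPlan(n_copies=10),
        "Copia1": CopyPlan(n_copies=10),
        "LINE1": CopyPlan(n_copies=10),
        "Helitron1": CopyPlan(n_copies=10),
    }
    gene_plan = GenePlan(
        class_counts={
            "A": 40, "B_LCN": 15, "B_HCN": 10,
            "C_STY_kinase": 4, "C_CaM_kinase": 4, "C_BTB_POZ": 4,
            "C_Sel1": 4, "C_Kelch": 4, "crinkler": 2, "transposon_related": 5,
        },
        near_mule_fraction=0.5,
    )
    srna_model = SrnaModel(n_genic_loci=8, n_unannotated_loci=20, n_mito_loci=4)
    cfg = SimulationConfig(
        seed=seed, n_chromosomes=2, chrom_length=150_000, mito_length=10_000,
        copy_plan=copy_plan, gene_plan=gene_plan, srna_model=srna_model,
        **overrides,
    )
    return cfg


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome(small_config(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_sites(rng):
    """Merged methylation sites on one chromosome for median/metagene oracles."""
    n = 2000
    pos = np.sort(rng.choice(np.arange(100_000), size=n, replace=False))
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos,
            "meth_freq": rng.random(n),
            "coverage": rng.integers(1, 50, size=n),
        }
    )
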