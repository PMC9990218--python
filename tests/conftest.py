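import numpy as np
import pandas as pd
import pytest

from mencna import PanelDesign, SimulationConfig, generate_panel
from mencna.panel import default_arm_table


@pytest.fixture(scope="session")
def full_panel():
    """Full-scale panel: 523 autosomal genes, 13,294 SNP loci."""
    return generate_panel(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_panel():
    """60-gene panel for fast unit tests."""
    return generate_panel(SimulationConfig(n_genes=60, n_snp_loci=1500, seed=2))


@pytest.fixture()
def toy_panel():
    """Hand-built 6-gene, 8-locus panel on two chromosomes."""
    arms = default_arm_table()
    genes = pd.DataFrame({
        "gene_id": ["A1", "A2", "A3", "B1", "B2", "B3"],
        "chrom": ["chr1"] * 3 + ["chr2"] * 3,
        "start": [1_000_000, 2_000_000, 3_000_000] * 2,
        "end": [1_020_000, 2_020_000, 3_020_000] * 2,
        "arm": ["p"] * 6,
    })
    loci = pd.DataFrame({
        "chrom": ["chr1"] * 4 + ["chr2"] * 4,
        "pos": [1_000_100, 1_000_200, 2_000_100, 3_000_100] * 2,
        "ref": ["A"] * 8, "alt": ["C"] * 8,
        "arm": ["p"] * 8,
        "gene_id": ["A1", "A1", "A2", "A3", "B1", "B1", "B2", "B3"],
    })
    return PanelDesign(genes=genes, snp_loci=loci, arms=arms)


def make_variant_table(rng: np.random.Generator, n: int = 200) -> pd.DataFrame:
    """Random variant records spanning every filter rule's territory."""
    return pd.DataFrame({
        "sample_id": rng.choice(["S1", "S2", "S3"], size=n),
        "gene_id": [f"G{int(i):04d}" for i in rng.integers(1, 50, size=n)],
        "chrom": rng.choice([f"chr{c}" for c in range(1, 23)], size=n),
        "pos": rng.integers(1, 10_000_000, size=n),
        "ref": rng.choice(list("ACGT"), size=n),
        "alt": rng.choice(list("ACGT"), size=n),
        "consequence": rng.choice(
            ["non_synonymous", "synonymous", "other"], size=n, p=[0.6, 0.3, 0.1]),
        "depth": rng.integers(10, 2000, size=n),
        "vaf": np.round(rng.uniform(0, 1, size=n), 4),
        "pop_freq": rng.choice([0.0, 5e-5, 1e-4, 5e-4, 1e-2], size=n),
    })
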