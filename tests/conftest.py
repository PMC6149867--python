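import pandas as pd
import pytest

from dioica.design import SampleDesign
from dioica.simulate import SimulationConfig, gene_lengths, simulate_dataset

# Published example: nine sex-segregating positions in five transcripts of a
# dioecious tree, genotyped in three females (F1-F3) and three males (M1-M3).
# Columns: gene, position, F1, F2, F3, M1, M2, M3.
SEG_TABLE_ROWS = [
    ("Cluster-47702.80936", 1101, "C", "C", "C", "G", "G", "G"),
    ("Cluster-47702.80197", 360, "T", "T", "T", "C", "C", "C"),
    ("Cluster-47702.80197", 460, "G", "G", "G", "A", "A", "A"),
    ("Cluster-47702.38156", 538, "T", "T", "T", "C", "C", "C"),
    ("Cluster-47702.38156", 596, "G", "G", "G", "T", "T", "T"),
    ("Cluster-47702.79497", 297, "A", "A", "A", "G", "G", "G"),
    ("Cluster-47702.79497", 312, "C", "C", "C", "T", "T", "T"),
    ("Cluster-47702.45188", 947, "T", "T", "T", "G", "G", "G"),
    ("Cluster-47702.45188", 968, "T", "T", "T", "C", "C", "C"),
]

SEG_TABLE_SAMPLES = [
    "EUCO_F1", "EUCO_F2", "EUCO_F3", "EUCO_M1", "EUCO_M2", "EUCO_M3",
]


def bare_config(**kwargs) -> SimulationConfig:
    """A SimulationConfig with nothing planted unless asked for."""
    base = dict(
        n_male_biased=0, n_female_biased=0,
        n_male_specific=0, n_female_specific=0,
        n_snp_sites=0, n_sex_segregating=0,
    )
    base.update(kwargs)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def published_design() -> SampleDesign:
    return SampleDesign.from_lists(
        males=SEG_TABLE_SAMPLES[3:], females=SEG_TABLE_SAMPLES[:3]
    )


@pytest.fixture(scope="session")
def published_genotype_table() -> pd.DataFrame:
    return pd.DataFrame(
        SEG_TABLE_ROWS, columns=["Gene_ID", "Position", *SEG_TABLE_SAMPLES]
    )


@pytest.fixture(scope="session")
def default_ds():
    """The default synthetic experiment (seed 1), shared across tests."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_lengths(default_ds) -> pd.Series:
    return gene_lengths(default_ds.unigenes)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast small-scale configuration for end-to-end tests."""
    return SimulationConfig(
        seed=7,
        n_genes=300,
        gene_length_range=(200, 800),
        n_male_biased=10,
        n_female_biased=5,
        n_male_specific=6,
        n_female_specific=4,
        n_snp_sites=30,
        n_sex_segregating=6,
        n_reads_per_sample=50,
    )
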