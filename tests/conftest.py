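import numpy as np
import pytest

from erclust.reads_io import GenomeModel, ReadSet
from erclust.synthetic_data import FeatureSpec, SimConfig, simulate


def make_readset(per_chrom, label="test", layout="single", fragment_hint=200):
    """Build a sorted ReadSet from {chrom: [(pos, strand), ...]}."""
    positions = {}
    strands = {}
    for chrom, rows in per_chrom.items():
        positions[chrom] = np.array([r[0] for r in rows], dtype=np.int64)
        strands[chrom] = np.array([r[1] for r in rows], dtype=np.int8)
    rs = ReadSet(
        sample_label=label,
        positions=positions,
        strands=strands,
        layout=layout,
        fragment_hint=fragment_hint,
    )
    rs.sort()
    return rs


@pytest.fixture
def small_genome():
    return GenomeModel(chrom_sizes={"chr1": 100_000, "chr2": 100_000})


@pytest.fixture(scope="session")
def five_chrom_genome():
    return GenomeModel(chrom_sizes={f"chr{i}": 500_000 for i in range(1, 6)})


@pytest.fixture(scope="session")
def peak_sim():
    """Medium single-peak simulation shared across tests (truth known)."""
    config = SimConfig(
        chrom_sizes={f"chr{i}": 500_000 for i in range(1, 6)},
        features=[FeatureSpec(kind="peak", count=75, width=250)],
        fragment_size=200,
        case_reads=100_000,
        control_reads=100_000,
        in_feature_fraction=0.6,
        seed=42,
    )
    return config, *simulate(config)


@pytest.fixture(scope="session")
def cluster_sim():
    """Clustered peaks plus isolated peaks (SER substrate)."""
    config = SimConfig(
        chrom_sizes={f"chr{i}": 500_000 for i in range(1, 6)},
        features=[
            FeatureSpec(kind="cluster", count=25, width=200, n_sub=4, gap=300),
            FeatureSpec(kind="peak", count=50, width=200),
        ],
        fragment_size=200,
        case_reads=125_000,
        control_reads=125_000,
        in_feature_fraction=0.6,
        seed=7,
    )
    return config, *simulate(config)


@pytest.fixture(scope="session")
def domain_sim():
    """Fragmented broad domains (LER substrate)."""
    config = SimConfig(
        chrom_sizes={f"chr{i}": 500_000 for i in range(1, 6)},
        features=[FeatureSpec(kind="domain", count=10, width=20_000, n_sub=10, gap=500)],
        fragment_size=200,
        case_reads=100_000,
        control_reads=100_000,
        in_feature_fraction=0.28,
        seed=11,
    )
    return config, *simulate(config)
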