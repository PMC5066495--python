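import numpy as np
import pytest
from hypothesis import settings

from bulkscan.config import PlantedQtl, ScanConfig, SimulationConfig
from bulkscan.variants import GeneModel, VariantSite

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def small_sim_config():
    """Two 8-Mb chromosomes, default study design, one planted locus."""
    return SimulationConfig(
        chrom_lengths={"A01": 8_000_000, "C02": 8_000_000},
        qtls=[PlantedQtl("C02", 4_000_000, 0.08, "q_test")],
        seed=11,
    )


@pytest.fixture
def scan_config():
    return ScanConfig(bulk_size=22, seed=0)


def make_site(chrom="A01", pos=100, ref="A", alt="G", be=(10, 35), bine=(30, 15),
              parents=True):
    samples = {"bulk_BE": be, "bulk_BinE": bine}
    if parents:
        samples["parent_QY10"] = (0, 18)
        samples["parent_W10"] = (18, 0)
    return VariantSite(chromosome=chrom, position=pos, ref=ref, alt=alt, samples=samples)


@pytest.fixture
def site_factory():
    return make_site


@pytest.fixture
def plus_gene():
    return GeneModel(
        gene_id="gplus", chromosome="A01", start=10_001, end=12_000, strand="+",
        cds_segments=[(10_001, 12_000)],
    )


def random_gene_set(rng: np.random.Generator, chrom: str, chrom_len: int, n: int):
    """Non-overlapping single-CDS genes for oracle tests."""
    genes = []
    slot = chrom_len // n
    for i in range(n):
        start = i * slot + int(rng.integers(1, slot // 4))
        length = int(rng.integers(10, 60)) * 3
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"g{i:03d}", chromosome=chrom, start=start,
                end=start + length - 1, strand=strand,
                cds_segments=[(start, start + length - 1)],
            )
        )
    return genes
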