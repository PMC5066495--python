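"""End-to-end orchestration of the synthetic study and the analysis.

Glues the stages together in memory: simulate a study (genome,
annotation, DH population, trait, bulks, read counts, expression),
scan it for QTL intervals, and run the candidate-gene funnel.  The CLI
and the test-suite recovery experiments both drive this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from bulkscan import integrate, qtlseq, simdata
from bulkscan.config import ScanConfig, SimulationConfig
from bulkscan.variants import GeneModel, VariantSite

logger = logging.getLogger(__name__)


@dataclass
class SyntheticStudy:
    """All artefacts of one simulated study."""

    config: SimulationConfig
    genome: dict[str, str] | None
    genes: list[GeneModel]
    population: simdata.DhPopulation
    phenotypes: list[simdata.PhenotypeRecord]
    high_bulk: list[str]
    low_bulk: list[str]
    sites: list[VariantSite]
    expression: pd.DataFrame | None


def simulate_study(
    config: SimulationConfig,
    gene_density: float = 25.0,
    planted_degs: Sequence[simdata.PlantedDeg] = (),
    with_genome_sequence: bool = False,
    with_expression: bool = True,
) -> SyntheticStudy:
    """Run every simulator stage under one config and seed.

    The genome sequence is only materialized when asked for (FASTA
    output or coding-effect analyses); the scan itself needs lengths
    only.
    """
    genome = simdata.generate_genome(config) if with_genome_sequence else None
    annotation_source = genome if genome is not None else config.chrom_lengths
    genes = simdata.generate_annotation(annotation_source, gene_density, config.seed + 10)
    pop = simdata.simulate_dh_population(config)
    phenos = simdata.simulate_phenotypes(pop, config)
    high_bulk, low_bulk = simdata.select_bulks(phenos, config.bulk_size)
    sites = simdata.simulate_bulk_reads(pop, (high_bulk, low_bulk), config, genome=genome)
    expression = None
    if with_expression:
        expression = simdata.simulate_expression(
            genes, planted_degs, seed=config.seed + 20
        )
    return SyntheticStudy(
        config=config,
        genome=genome,
        genes=genes,
        population=pop,
        phenotypes=phenos,
        high_bulk=high_bulk,
        low_bulk=low_bulk,
        sites=sites,
        expression=expression,
    )


@dataclass
class StudyResult:
    """Scan + funnel outcome for one study."""

    records: list[qtlseq.SnpIndexRecord]
    dropped: dict[str, int]
    windows: list[qtlseq.WindowStat]
    intervals: list[qtlseq.QtlInterval]
    candidates: dict[str, list[integrate.CandidateGene]] = field(default_factory=dict)
    funnel: list[integrate.FunnelReport] = field(default_factory=list)


def analyze_study(
    study: SyntheticStudy,
    scan_config: ScanConfig | None = None,
    mode: str = integrate.MODE_ROOT_UNIQUE,
) -> StudyResult:
    """Scan a simulated study and, when expression is present, run the
    candidate funnel on every called interval."""
    cfg = scan_config or ScanConfig(bulk_size=study.config.bulk_size,
                                    seed=study.config.seed)
    records, dropped, windows, intervals = qtlseq.scan(
        study.sites, cfg, study.config.chrom_lengths
    )
    result = StudyResult(
        records=records, dropped=dropped, windows=windows, intervals=intervals
    )
    if study.expression is not None and intervals:
        result.candidates, result.funnel = integrate.run_funnel(
            intervals, study.genes, study.expression, mode=mode
        )
    return result
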