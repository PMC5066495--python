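"""Synthetic study generator.

Builds every input the analysis consumes — genome (FASTA), gene models
(GFF3), a doubled-haploid (DH) mapping population, a low-boron
dry-biomass trait, extreme-phenotype bulks, pooled sequencing read
counts (VCF with per-sample allelic depths), and per-tissue
differential-expression tables (TSV) — with the statistical structure
the downstream scan assumes.

Population model
----------------
Each DH line is one recombinant gamete of the F1 between two fully
homozygous parents, then chromosome-doubled, so every line is
homozygous at every marker and parental alleles segregate 1:1.
Crossovers per chromosome are Poisson with mean equal to the genetic
length in Morgans (Haldane model, no interference), positions uniform.

Allele encoding
---------------
The B-efficient parent's allele is encoded as the VCF ALT allele and
the B-inefficient parent's as REF.  With SNP-index = alt/total and
Δ(SNP-index) = index(BE bulk) − index(BinE bulk), a locus whose
trait-raising allele comes from the B-efficient parent then scans
positive and one raised by the B-inefficient parent scans negative,
matching the sign → contributing-parent convention used when calling
intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from bulkscan.config import (
    SAMPLE_BULK_BE,
    SAMPLE_BULK_BINE,
    SAMPLE_PARENT_BE,
    SAMPLE_PARENT_BINE,
    ConfigError,
    SimulationConfig,
)
from bulkscan.integrate import adjust_fdr
from bulkscan.variants import GeneModel, VariantSite

logger = logging.getLogger(__name__)

_BASE_LOOKUP = np.frombuffer(b"ACGT", dtype="S1")

#: Genotype codes: 1 = allele from the B-efficient parent (VCF ALT),
#: 0 = allele from the B-inefficient parent (VCF REF).
ALLELE_BE = 1
ALLELE_BINE = 0


@dataclass
class DhPopulation:
    """A doubled-haploid population: homozygous genotypes at SNP markers.

    ``genotypes[chrom]`` is an (n_lines, n_markers) int8 array of
    :data:`ALLELE_BE` / :data:`ALLELE_BINE` codes; every line is
    homozygous at every marker by construction.
    """

    line_ids: list[str]
    marker_positions: dict[str, np.ndarray]
    genotypes: dict[str, np.ndarray]

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def allele_frequency(self, chrom: str) -> np.ndarray:
        """Per-marker frequency of the B-efficient parent's allele."""
        return self.genotypes[chrom].mean(axis=0)


@dataclass
class PhenotypeRecord:
    """Per-line trait record: dry biomass under low and high B, and BEC.

    BEC (B-efficiency coefficient) = dry weight under low B divided by
    dry weight under high B.
    """

    line_id: str
    dw_low_b: float
    dw_high_b: float

    def __post_init__(self) -> None:
        if self.dw_low_b < 0 or self.dw_high_b < 0:
            raise ValueError("dry weights must be non-negative")

    @property
    def bec(self) -> float:
        return self.dw_low_b / self.dw_high_b if self.dw_high_b > 0 else float("nan")


@dataclass(frozen=True)
class PlantedDeg:
    """A differential-expression signal planted by the simulator.

    ``direction`` says which genotype's transcript level is raised:
    ``"Q>W"`` boosts the B-efficient genotype, ``"W>Q"`` the
    B-inefficient one, in each listed tissue.
    """

    gene_id: str
    tissues: tuple[str, ...] = ("root",)
    direction: str = "W>Q"
    fold: float = 8.0

    def __post_init__(self) -> None:
        if self.direction not in ("Q>W", "W>Q"):
            raise ValueError(f"direction must be 'Q>W' or 'W>Q', got {self.direction!r}")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        for t in self.tissues:
            if t not in ("shoot", "root"):
                raise ValueError(f"unknown tissue {t!r}")


# ---------------------------------------------------------------------------
# Genome & annotation
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> dict[str, str]:
    """Random nucleotide sequences of the configured chromosome lengths."""
    rng = np.random.default_rng(config.seed)
    genome: dict[str, str] = {}
    for name, length in config.chrom_lengths.items():
        if length <= 0:
            raise ConfigError(f"chromosome {name!r} has non-positive length {length}")
        idx = rng.integers(0, 4, size=length)
        genome[name] = _BASE_LOOKUP[idx].tobytes().decode("ascii")
    return genome


def generate_annotation(
    genome: dict[str, str] | dict[str, int],
    gene_density: float,
    seed: int,
    max_attempts_per_gene: int = 200,
) -> list[GeneModel]:
    """Place non-overlapping gene models at ``gene_density`` genes/Mb.

    Each gene gets a random strand, a 1.5–4.5 kb span and 1–3 CDS
    segments whose total length is divisible by 3.  Placement is
    rejection sampling; an impossible density raises after bounded
    retries.
    """
    if gene_density <= 0:
        raise ConfigError("gene_density must be positive")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    for chrom, value in genome.items():
        length = len(value) if isinstance(value, str) else int(value)
        n_genes = max(1, int(round(gene_density * length / 1e6)))
        occupied: list[tuple[int, int]] = []
        placed = 0
        attempts = 0
        budget = max_attempts_per_gene * n_genes
        while placed < n_genes:
            if attempts >= budget:
                raise ConfigError(
                    f"could not place {n_genes} genes on {chrom} "
                    f"({length} bp) after {budget} attempts; lower gene_density"
                )
            attempts += 1
            span = int(rng.integers(1500, 4501))
            if span >= length:
                span = max(90, length // 2)
            start = int(rng.integers(1, length - span + 1))
            end = start + span - 1
            if any(s <= end and start <= e for s, e in occupied):
                continue
            occupied.append((start, end))
            placed += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene_{chrom}_{placed:04d}_{start}",
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    cds_segments=_random_cds(rng, start, end),
                )
            )
    genes.sort(key=lambda g: (g.chromosome, g.start))
    # re-number in coordinate order for stable, readable IDs
    renamed: list[GeneModel] = []
    counter: dict[str, int] = {}
    for g in genes:
        counter[g.chromosome] = counter.get(g.chromosome, 0) + 1
        renamed.append(
            GeneModel(
                gene_id=f"gene_{g.chromosome}_{counter[g.chromosome]:04d}",
                chromosome=g.chromosome,
                start=g.start,
                end=g.end,
                strand=g.strand,
                cds_segments=g.cds_segments,
            )
        )
    return renamed


def _random_cds(rng: np.random.Generator, start: int, end: int) -> list[tuple[int, int]]:
    """1–3 non-overlapping CDS segments inside [start, end], each a
    multiple of 3 bp so the spliced CDS translates cleanly."""
    span = end - start + 1
    n_seg = int(rng.integers(1, 4)) if span >= 600 else 1
    bounds = np.linspace(start, end + 1, n_seg + 1).astype(int)
    segments: list[tuple[int, int]] = []
    for i in range(n_seg):
        lo, hi = bounds[i], bounds[i + 1] - 1
        room = hi - lo + 1
        seg_len = min(room - room % 3, max(30, (room // 2) - (room // 2) % 3))
        seg_len = max(seg_len - seg_len % 3, 3)
        offset = int(rng.integers(0, room - seg_len + 1))
        s = lo + offset
        segments.append((s, s + seg_len - 1))
    return segments


# ---------------------------------------------------------------------------
# Population, trait, bulks
# ---------------------------------------------------------------------------

def simulate_dh_population(config: SimulationConfig) -> DhPopulation:
    """Simulate a DH population by Haldane recombination of two
    homozygous parental haplotypes, then chromosome doubling."""
    rng = np.random.default_rng(config.seed + 1)
    line_ids = [f"DH{i + 1:03d}" for i in range(config.n_lines)]
    marker_positions: dict[str, np.ndarray] = {}
    genotypes: dict[str, np.ndarray] = {}
    for chrom, length in config.chrom_lengths.items():
        pos = np.arange(config.marker_spacing, length + 1, config.marker_spacing)
        if pos.size == 0:
            pos = np.array([max(1, length // 2)])
        marker_positions[chrom] = pos
        morgans = config.cm_per_mb * (length / 1e6) / 100.0
        geno = np.empty((config.n_lines, pos.size), dtype=np.int8)
        n_xo = rng.poisson(morgans, size=config.n_lines)
        starts = rng.integers(0, 2, size=config.n_lines)
        for i in range(config.n_lines):
            if n_xo[i] == 0:
                geno[i, :] = starts[i]
                continue
            xo = np.sort(rng.uniform(1, length + 1, size=n_xo[i]))
            # parity of crossovers left of each marker flips the phase
            geno[i, :] = (starts[i] + np.searchsorted(xo, pos, side="right")) % 2
        genotypes[chrom] = geno
    return DhPopulation(line_ids=line_ids, marker_positions=marker_positions,
                        genotypes=genotypes)


def _snap_qtls(pop: DhPopulation, config: SimulationConfig) -> list[tuple[str, int, float]]:
    """Snap each planted QTL to the nearest simulated marker index."""
    snapped = []
    for q in config.qtls:
        if q.chromosome not in pop.marker_positions:
            raise ConfigError(f"QTL {q.label!r} on unknown chromosome {q.chromosome!r}")
        pos = pop.marker_positions[q.chromosome]
        idx = int(np.argmin(np.abs(pos.astype(np.int64) - q.position)))
        snapped.append((q.chromosome, idx, q.effect))
    return snapped


def simulate_phenotypes(
    pop: DhPopulation, config: SimulationConfig
) -> list[PhenotypeRecord]:
    """Simulate the low-B dry-biomass trait and its high-B counterpart.

    dw_low_b = (baseline + Σ QTL effects of B-efficient-parent alleles)
    × lognormal noise, with the noise variance chosen so the realized
    coefficient of variation of the trait matches ``trait_cv``
    (accounting for the variance the planted QTLs already contribute);
    values are then truncated to ``trait_range``.  High-B biomass is
    drawn around the top of the trait range, unaffected by the planted
    low-B loci, and BEC follows as the low/high ratio.
    """
    rng = np.random.default_rng(config.seed + 2)
    snapped = _snap_qtls(pop, config)
    lo, hi = config.trait_range
    gm = float(np.sqrt(lo * hi)) if lo > 0 else hi / 4.0

    genetic = np.zeros(pop.n_lines)
    for chrom, idx, effect in snapped:
        genetic += effect * (pop.genotypes[chrom][:, idx] == ALLELE_BE)
    total_effect = sum(e for _, _, e in snapped)
    baseline = max(gm - 0.5 * total_effect, 0.05 * gm)
    values = baseline + genetic
    if np.any(values <= 0):
        raise ConfigError("planted QTL effects drive the baseline trait below zero")

    if config.trait_cv > 0:
        cv_target_sq = config.trait_cv**2
        mean_g = values.mean()
        cv_genetic_sq = values.var() / mean_g**2 if mean_g > 0 else 0.0
        ratio = (1.0 + cv_target_sq) / (1.0 + cv_genetic_sq)
        sigma = float(np.sqrt(np.log(ratio))) if ratio > 1.0 else 0.0
        if sigma > 0:
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=pop.n_lines))
            values = values * noise
    values = np.clip(values, lo, hi)

    high = hi * np.exp(rng.normal(0.0, 0.1, size=pop.n_lines))
    return [
        PhenotypeRecord(line_id=lid, dw_low_b=float(v), dw_high_b=float(h))
        for lid, v, h in zip(pop.line_ids, values, high)
    ]


def select_bulks(
    phenos: Sequence[PhenotypeRecord], bulk_size: int
) -> tuple[list[str], list[str]]:
    """Select the high (B-efficient) and low (B-inefficient) bulks.

    Lines are ordered by low-B dry biomass ascending with line_id as the
    deterministic tie-break; the bottom ``bulk_size`` lines form the low
    bulk and the top ``bulk_size`` the high bulk, so the two sets are
    disjoint even when all phenotypes tie.
    """
    if bulk_size > len(phenos) // 2:
        raise ConfigError(
            f"bulk_size {bulk_size} exceeds half the population ({len(phenos)} lines)"
        )
    ordered = sorted(phenos, key=lambda p: (p.dw_low_b, p.line_id))
    low = [p.line_id for p in ordered[:bulk_size]]
    high = [p.line_id for p in ordered[-bulk_size:]]
    return high, low


def simulate_bulk_reads(
    pop: DhPopulation,
    bulks: tuple[Sequence[str], Sequence[str]],
    config: SimulationConfig,
    genome: dict[str, str] | None = None,
) -> list[VariantSite]:
    """Simulate pooled sequencing read counts at every marker.

    Per marker and bulk, the true ALT (B-efficient-parent allele)
    frequency is the fraction of bulk lines carrying it; site depth is
    Poisson(``bulk_depth``) and ALT reads Binomial(depth, frequency).
    Parents are emitted as fixed opposite homozygotes at
    Poisson(``parent_depth``).
    """
    high_bulk, low_bulk = bulks
    if set(high_bulk) & set(low_bulk):
        raise ConfigError("bulks must be disjoint")
    rng = np.random.default_rng(config.seed + 3)
    line_index = {lid: i for i, lid in enumerate(pop.line_ids)}
    hi_idx = np.array([line_index[l] for l in high_bulk])
    lo_idx = np.array([line_index[l] for l in low_bulk])

    sites: list[VariantSite] = []
    for chrom, positions in pop.marker_positions.items():
        geno = pop.genotypes[chrom]
        f_hi = (geno[hi_idx, :] == ALLELE_BE).mean(axis=0)
        f_lo = (geno[lo_idx, :] == ALLELE_BE).mean(axis=0)
        n = positions.size
        d_hi = rng.poisson(config.bulk_depth, size=n)
        d_lo = rng.poisson(config.bulk_depth, size=n)
        a_hi = rng.binomial(d_hi, f_hi)
        a_lo = rng.binomial(d_lo, f_lo)
        d_pq = rng.poisson(config.parent_depth, size=n)
        d_pw = rng.poisson(config.parent_depth, size=n)
        seq = genome.get(chrom) if genome else None
        ref_choices = rng.integers(0, 4, size=n)
        alt_shift = rng.integers(1, 4, size=n)
        for j, posn in enumerate(positions):
            if seq is not None:
                ref = seq[int(posn) - 1]
                ref_code = b"ACGT".index(ref.encode())
            else:
                ref_code = int(ref_choices[j])
                ref = "ACGT"[ref_code]
            alt = "ACGT"[(ref_code + int(alt_shift[j])) % 4]
            sites.append(
                VariantSite(
                    chromosome=chrom,
                    position=int(posn),
                    ref=ref,
                    alt=alt,
                    samples={
                        SAMPLE_PARENT_BE: (0, int(d_pq[j])),
                        SAMPLE_PARENT_BINE: (int(d_pw[j]), 0),
                        SAMPLE_BULK_BE: (int(d_hi[j] - a_hi[j]), int(a_hi[j])),
                        SAMPLE_BULK_BINE: (int(d_lo[j] - a_lo[j]), int(a_lo[j])),
                    },
                )
            )
    return sites


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

EXPRESSION_COLUMNS = ["gene_id", "tissue", "mean_q", "mean_w", "p", "fdr", "direction"]


def simulate_expression(
    annotation: Sequence[GeneModel],
    planted_candidates: Sequence[PlantedDeg],
    seed: int,
    tissues: Sequence[str] = ("shoot", "root"),
    n_replicates: int = 3,
    noise_sd: float = 0.25,
    base_log_mean: float = 3.0,
    base_log_sd: float = 1.0,
) -> pd.DataFrame:
    """Simulate a per-gene, per-tissue expression comparison table.

    Abundances for both genotypes are drawn from a shared log-normal
    null with ``n_replicates`` replicates each; planted candidates get a
    ``fold``-change in their configured tissue(s) and direction.  The
    p-value is a two-sided moderated two-sample test on log abundances:
    the within-group variance is pooled across all genes of a tissue
    (the standard remedy for tiny replicate counts, full-shrinkage
    limma-style), giving 2·(n_replicates−1)·n_genes degrees of freedom.
    Under the null the p-values are exactly calibrated.  The FDR is
    Benjamini–Hochberg within tissue.
    """
    gene_ids = [g.gene_id for g in annotation]
    known = set(gene_ids)
    planted_map: dict[tuple[str, str], PlantedDeg] = {}
    for c in planted_candidates:
        if c.gene_id not in known:
            raise ValueError(f"planted candidate {c.gene_id!r} absent from annotation")
        for t in c.tissues:
            planted_map[(c.gene_id, t)] = c

    rng = np.random.default_rng(seed)
    n_genes = len(gene_ids)
    n = n_replicates
    rows: list[dict] = []
    for tissue in tissues:
        base = rng.normal(base_log_mean, base_log_sd, size=n_genes)
        shift_q = np.zeros(n_genes)
        shift_w = np.zeros(n_genes)
        for gi, gene_id in enumerate(gene_ids):
            planted = planted_map.get((gene_id, tissue))
            if planted is not None:
                if planted.direction == "Q>W":
                    shift_q[gi] = np.log(planted.fold)
                else:
                    shift_w[gi] = np.log(planted.fold)
        noise = noise_sd if noise_sd > 0 else 0.0
        log_q = base[:, None] + shift_q[:, None] + rng.normal(0.0, 1.0, (n_genes, n)) * noise
        log_w = base[:, None] + shift_w[:, None] + rng.normal(0.0, 1.0, (n_genes, n)) * noise
        diff = log_q.mean(axis=1) - log_w.mean(axis=1)
        if n > 1:
            s2_pooled = 0.5 * (log_q.var(axis=1, ddof=1) + log_w.var(axis=1, ddof=1)).mean()
        else:
            s2_pooled = 0.0
        df = 2 * (n - 1) * n_genes
        if s2_pooled > 0 and df > 0:
            t_stat = diff / np.sqrt(2.0 * s2_pooled / n)
            p = 2.0 * stats.t.sf(np.abs(t_stat), df)
        else:
            p = np.where(diff == 0.0, 1.0, 0.0)
        mean_q = np.exp(log_q).mean(axis=1)
        mean_w = np.exp(log_w).mean(axis=1)
        for gi, gene_id in enumerate(gene_ids):
            rows.append(
                {
                    "gene_id": gene_id,
                    "tissue": tissue,
                    "mean_q": float(mean_q[gi]),
                    "mean_w": float(mean_w[gi]),
                    "p": float(p[gi]),
                    "direction": "Q>W" if mean_q[gi] > mean_w[gi] else "W>Q",
                }
            )
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    for tissue in tissues:
        mask = table["tissue"] == tissue
        table.loc[mask, "fdr"] = adjust_fdr(table.loc[mask, "p"].to_numpy())
    return table[EXPRESSION_COLUMNS]


def write_expression_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(EXPRESSION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"expression table {path} lacks columns: {sorted(missing)}")
    return table
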