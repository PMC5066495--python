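"""Variant and annotation handling plus variant-landscape summaries.

This module owns the on-disk interchange formats (VCF v4.2 with
per-sample allelic depths, GFF3 gene models, FASTA genomes) and the
classification layer of the analysis: transition/transversion typing,
the InDel length spectrum, strand-aware genomic-feature assignment
(genic / 2-kb promoter / 1-kb downstream / intergenic), and
synonymous vs non-synonymous calls for coding SNPs.

Coordinates are 1-based inclusive at every external interface (VCF and
GFF3 convention); the few places that need 0-based offsets convert
locally.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
BASES = frozenset("ACGT")

#: The two transition pairs; the remaining four unordered pairs are
#: transversions.
TRANSITION_PAIRS = frozenset({"A/G", "C/T"})
ALL_SUBTYPES = ("A/G", "C/T", "A/C", "A/T", "C/G", "G/T")

FEATURE_GENIC = "genic"
FEATURE_PROMOTER = "promoter_2kb_upstream"
FEATURE_DOWNSTREAM = "downstream_1kb"
FEATURE_INTERGENIC = "intergenic"
PROMOTER_SPAN = 2_000
DOWNSTREAM_SPAN = 1_000


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be parsed or lacks required fields."""


@dataclass
class VariantSite:
    """One biallelic variant with per-sample (ref, alt) read counts.

    ``samples`` maps sample name to a pair of non-negative integers:
    reads supporting REF and reads supporting ALT.
    """

    chromosome: str
    position: int  # 1-based, VCF convention
    ref: str
    alt: str
    samples: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or set(allele) - BASES:
                raise ValueError(f"{name} allele {allele!r} is not a DNA string")
        if "," in self.alt:
            raise ValueError("VariantSite is biallelic; split multi-allelic records")
        for sample, (r, a) in self.samples.items():
            if r < 0 or a < 0:
                raise ValueError(f"negative read count for sample {sample!r}")

    @property
    def kind(self) -> str:
        """``SNP``, ``insertion`` (alt longer) or ``deletion`` (ref longer)."""
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNP"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    def depth(self, sample: str) -> int:
        r, a = self.samples[sample]
        return r + a


@dataclass(frozen=True)
class SubstitutionClass:
    """Transition/transversion class and unordered base-pair subtype."""

    klass: str  # "transition" | "transversion"
    subtype: str  # e.g. "A/G"


@dataclass
class GeneModel:
    """A protein-coding gene with its CDS segments.

    ``start``/``end`` are 1-based inclusive; ``cds_segments`` is the
    ascending-coordinate list of (start, end) pairs. On the minus strand
    the coding order is the reverse complement of that concatenation.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    cds_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        self.cds_segments = sorted(tuple(s) for s in self.cds_segments)
        for s, e in self.cds_segments:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: CDS segment ({s},{e}) outside span")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """3' end of the gene (strand-aware)."""
        return self.end if self.strand == "+" else self.start


# ---------------------------------------------------------------------------
# FASTA / GFF3 / VCF input & output
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene and CDS features as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start)):
            fh.write(
                f"{g.chromosome}\tbulkscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds_segments, start=1):
                fh.write(
                    f"{g.chromosome}\tbulkscan\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + CDS children) from a GFF3 file."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        cds = [(c.start, c.end) for c in db.children(feat, featuretype="CDS")]
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                cds_segments=cds,
            )
        )
    genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return genes


def write_vcf(
    sites: Sequence[VariantSite],
    path: str | Path,
    sample_order: Sequence[str] | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write sites as uncompressed VCF v4.2 with a per-sample AD field."""
    if sample_order is None:
        sample_order = list(sites[0].samples) if sites else []
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths for the ref and alt alleles">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_order)
    )
    for site in sites:
        cols = [
            site.chromosome,
            str(site.position),
            ".",
            site.ref,
            site.alt,
            ".",
            "PASS",
            ".",
            "AD",
        ]
        for sample in sample_order:
            r, a = site.samples[sample]
            cols.append(f"{r},{a}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(
    path: str | Path,
    required_samples: Sequence[str] | None = None,
    multiallelic: str = "skip",
) -> list[VariantSite]:
    """Read biallelic sites with per-sample AD counts from a VCF.

    Parameters
    ----------
    required_samples:
        Sample names that must be present with AD counts; a missing
        sample raises :class:`VcfParseError` naming it.
    multiallelic:
        ``"skip"`` (default) drops records with >1 ALT allele with a
        logged warning; ``"split"`` emits one biallelic site per ALT
        allele (ref count shared); ``"error"`` raises.
    """
    if multiallelic not in ("skip", "split", "error"):
        raise ValueError(f"unknown multiallelic policy {multiallelic!r}")
    # htslib is lenient about some malformed records (it logs and yields
    # garbage); a light structural pass gives precise line-numbered errors
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise VcfParseError(f"{path} line {i}: fewer than 8 columns")
            if not fields[1].isdigit():
                raise VcfParseError(
                    f"{path} line {i}: position field {fields[1]!r} is not an integer"
                )
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - htslib error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    names = list(vcf.samples)
    if required_samples:
        for s in required_samples:
            if s not in names:
                raise VcfParseError(f"required sample {s!r} absent from VCF {path}")
    sites: list[VariantSite] = []
    lineno = 0  # data-record counter, for error messages
    try:
        for v in vcf:
            lineno += 1
            alts = v.ALT
            if len(alts) != 1:
                if multiallelic == "error":
                    raise VcfParseError(
                        f"multi-allelic record at {v.CHROM}:{v.POS} (record {lineno})"
                    )
                if multiallelic == "skip":
                    logger.warning(
                        "skipping multi-allelic record %s:%s (record %d)",
                        v.CHROM, v.POS, lineno,
                    )
                    continue
            ad = v.format("AD")
            if ad is None:
                raise VcfParseError(
                    f"record {v.CHROM}:{v.POS} (record {lineno}) lacks AD counts"
                )
            for alt_idx, alt in enumerate(alts, start=1):
                samples: dict[str, tuple[int, int]] = {}
                for i, name in enumerate(names):
                    row = ad[i]
                    ref_n = int(row[0]) if row[0] >= 0 else 0
                    alt_n = int(row[alt_idx]) if len(row) > alt_idx and row[alt_idx] >= 0 else 0
                    samples[name] = (ref_n, alt_n)
                if required_samples:
                    for s in required_samples:
                        if s not in samples:
                            raise VcfParseError(f"sample {s!r} missing AD at record {lineno}")
                sites.append(
                    VariantSite(
                        chromosome=v.CHROM,
                        position=v.POS,
                        ref=v.REF,
                        alt=str(alt),
                        samples=samples,
                    )
                )
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"malformed VCF record near data line {lineno + 1} of {path}: {exc}"
        ) from exc
    return sites


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_substitution(ref: str, alt: str) -> SubstitutionClass:
    """Type a single-base substitution as transition or transversion.

    Transitions are purine<->purine or pyrimidine<->pyrimidine changes
    (unordered pairs A/G and C/T); the four remaining pairs (A/C, A/T,
    C/G, G/T) are transversions.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"alleles must be single bases in ACGT, got {ref!r}->{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r})")
    subtype = "/".join(sorted((ref, alt)))
    klass = "transition" if subtype in TRANSITION_PAIRS else "transversion"
    return SubstitutionClass(klass=klass, subtype=subtype)


def indel_length(site: VariantSite) -> int:
    """InDel length = absolute ref/alt length difference."""
    if site.kind == "SNP":
        raise ValueError(f"site {site.chromosome}:{site.position} is a SNP, not an InDel")
    return abs(len(site.ref) - len(site.alt))


def indel_spectrum(sites: Iterable[VariantSite]) -> dict[int, int]:
    """Count InDels by length; raises if a SNP slips in."""
    return dict(Counter(indel_length(s) for s in sites))


def spectrum_percentages(spectrum: dict[int, int], decimals: int = 1) -> dict[int, float]:
    total = sum(spectrum.values())
    if total == 0:
        return {}
    return {k: round(100.0 * v / total, decimals) for k, v in sorted(spectrum.items())}


class _GeneIndex:
    """Sorted-start index over one chromosome's genes for feature lookup."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = sorted(genes, key=lambda g: (g.start, g.gene_id))
        self.starts = [g.start for g in self.genes]
        self.max_len = max((g.end - g.start + 1 for g in self.genes), default=0)

    def near(self, pos: int, pad: int) -> list[GeneModel]:
        """Genes whose padded span could contain ``pos``."""
        lo = bisect_left(self.starts, pos - pad - self.max_len)
        hi = bisect_right(self.starts, pos + pad)
        return self.genes[lo:hi]


def assign_genomic_feature(
    position: int,
    genes: Sequence[GeneModel] | _GeneIndex,
    chrom_length: int,
) -> str:
    """Assign a position to genic / promoter / downstream / intergenic.

    Precedence is genic > promoter (2 kb upstream of the TSS,
    strand-aware) > downstream (1 kb past the 3' end, strand-aware) >
    intergenic.  When two genes' flanks overlap the nearer gene wins;
    remaining ties break on gene_id.  Genes must all lie on the queried
    chromosome.
    """
    if not 1 <= position <= chrom_length:
        raise ValueError(f"position {position} outside chromosome of length {chrom_length}")
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(genes)
    candidates = index.near(position, PROMOTER_SPAN)
    promoter_hits: list[tuple[int, str]] = []
    downstream_hits: list[tuple[int, str]] = []
    for g in candidates:
        if g.start <= position <= g.end:
            return FEATURE_GENIC
        if g.strand == "+":
            if g.start - PROMOTER_SPAN <= position < g.start:
                promoter_hits.append((g.start - position, g.gene_id))
            if g.end < position <= g.end + DOWNSTREAM_SPAN:
                downstream_hits.append((position - g.end, g.gene_id))
        else:
            if g.end < position <= g.end + PROMOTER_SPAN:
                promoter_hits.append((position - g.end, g.gene_id))
            if g.start - DOWNSTREAM_SPAN <= position < g.start:
                downstream_hits.append((g.start - position, g.gene_id))
    if promoter_hits:
        return FEATURE_PROMOTER
    if downstream_hits:
        return FEATURE_DOWNSTREAM
    return FEATURE_INTERGENIC


def spliced_cds(gene: GeneModel, chrom_seq: str) -> str:
    """Coding sequence of a gene, 5'->3' (reverse-complemented on -)."""
    parts = [chrom_seq[s - 1 : e] for s, e in gene.cds_segments]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def _cds_offset(gene: GeneModel, position: int) -> int | None:
    """0-based coding-sequence offset of a genomic position, or None."""
    offset = 0
    ascending = None
    for s, e in gene.cds_segments:
        if s <= position <= e:
            ascending = offset + (position - s)
            break
        offset += e - s + 1
    if ascending is None:
        return None
    if gene.strand == "+":
        return ascending
    return gene.cds_length - 1 - ascending


def classify_coding_effect(site: VariantSite, gene: GeneModel, chrom_seq: str) -> str:
    """Call a CDS SNP ``synonymous`` or ``non-synonymous``.

    Splices the CDS strand-aware, substitutes the alternate base and
    translates the affected codon with the standard genetic code.
    """
    if site.kind != "SNP":
        raise ValueError("coding-effect classification is defined for SNPs only")
    if gene.cds_length % 3 != 0:
        raise ValueError(f"gene {gene.gene_id}: CDS length not divisible by 3")
    pos = _cds_offset(gene, site.position)
    if pos is None:
        raise ValueError(
            f"SNP {site.chromosome}:{site.position} outside CDS of {gene.gene_id}"
        )
    cds = spliced_cds(gene, chrom_seq)
    base = site.alt if gene.strand == "+" else str(Seq(site.alt).complement())
    ref_base = site.ref if gene.strand == "+" else str(Seq(site.ref).complement())
    if cds[pos] != ref_base:
        raise ValueError(
            f"reference mismatch at {site.chromosome}:{site.position} in {gene.gene_id}: "
            f"CDS has {cds[pos]!r}, site ref is {site.ref!r}"
        )
    codon_i = pos // 3
    codon = cds[3 * codon_i : 3 * codon_i + 3]
    mutated = codon[: pos % 3] + base + codon[pos % 3 + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    return "synonymous" if aa_ref == aa_alt else "non-synonymous"


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def percentage(count: float, total: float, decimals: int = 1) -> float:
    """Percentage rounded to the printed precision (default 1 decimal)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


def mean_per_chromosome(total: int, n_chromosomes: int) -> int:
    """Mean count per chromosome, rounded to the nearest integer."""
    if n_chromosomes <= 0:
        raise ValueError("n_chromosomes must be positive")
    return int(round(total / n_chromosomes))


def ts_tv_ratio(ts_count: int, tv_count: int, decimals: int = 1) -> float:
    """Transition/transversion ratio, rounded (one decimal by default)."""
    if tv_count <= 0:
        raise ValueError("tv_count must be positive")
    return round(ts_count / tv_count, decimals)


def snp_frequency_bp(chrom_length: int, snp_count: int) -> int:
    """'1 SNP per N bp' denominator: round(length / count)."""
    if snp_count <= 0:
        raise ValueError("snp_count must be positive")
    return int(round(chrom_length / snp_count))


def nucleotide_diversity(snp_count: int, chrom_length: int) -> float:
    """SNPs per nucleotide of assembled sequence (count / length)."""
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    return snp_count / chrom_length


@dataclass
class VariantSummary:
    """Landscape summary of a variant set against a genome + annotation."""

    snps_per_chromosome: dict[str, int]
    indels_per_chromosome: dict[str, int]
    mean_snps_per_chromosome: int
    snp_frequency_bp_per_chromosome: dict[str, int]
    pi_per_chromosome: dict[str, float]
    ts_count: int
    tv_count: int
    subtype_counts: dict[str, int]
    indel_length_spectrum: dict[int, int]
    feature_counts: dict[str, int]
    synonymous_count: int
    nonsynonymous_count: int

    @property
    def total_snps(self) -> int:
        return sum(self.snps_per_chromosome.values())

    @property
    def total_indels(self) -> int:
        return sum(self.indels_per_chromosome.values())

    @property
    def ts_tv(self) -> float:
        return ts_tv_ratio(self.ts_count, self.tv_count)

    def subtype_percentages(self) -> dict[str, float]:
        total = self.total_snps
        return {k: percentage(v, total) for k, v in self.subtype_counts.items()}


def summarize_variants(
    sites: Sequence[VariantSite],
    genome: dict[str, str] | dict[str, int],
    genes: Sequence[GeneModel] = (),
) -> VariantSummary:
    """Compute the full variant-landscape summary.

    ``genome`` maps chromosome name to either the sequence string or
    the length in bp; sequences are required only for coding-effect
    calls (skipped when lengths alone are given).
    """
    lengths = {
        name: (len(v) if isinstance(v, str) else int(v)) for name, v in genome.items()
    }
    have_seq = all(isinstance(v, str) for v in genome.values())
    for s in sites:
        if s.chromosome not in lengths:
            raise ValueError(f"site chromosome {s.chromosome!r} absent from genome")

    snps = [s for s in sites if s.kind == "SNP"]
    indels = [s for s in sites if s.kind != "SNP"]

    snp_counts = {name: 0 for name in lengths}
    indel_counts = {name: 0 for name in lengths}
    for s in snps:
        snp_counts[s.chromosome] += 1
    for s in indels:
        indel_counts[s.chromosome] += 1

    subtype_counts = {sub: 0 for sub in ALL_SUBTYPES}
    ts = tv = 0
    for s in snps:
        cls = classify_substitution(s.ref, s.alt)
        subtype_counts[cls.subtype] += 1
        if cls.klass == "transition":
            ts += 1
        else:
            tv += 1

    genes_by_chrom: dict[str, _GeneIndex] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chromosome, None)
    for chrom in genes_by_chrom:
        genes_by_chrom[chrom] = _GeneIndex([g for g in genes if g.chromosome == chrom])
    feature_counts = {
        FEATURE_GENIC: 0,
        FEATURE_PROMOTER: 0,
        FEATURE_DOWNSTREAM: 0,
        FEATURE_INTERGENIC: 0,
    }
    for s in sites:
        idx = genes_by_chrom.get(s.chromosome)
        feat = assign_genomic_feature(
            s.position, idx if idx is not None else [], lengths[s.chromosome]
        )
        feature_counts[feat] += 1

    syn = nonsyn = 0
    if have_seq and genes:
        for s in snps:
            idx = genes_by_chrom.get(s.chromosome)
            if idx is None:
                continue
            for g in idx.near(s.position, 0):
                if _cds_offset(g, s.position) is not None:
                    effect = classify_coding_effect(s, g, genome[s.chromosome])
                    if effect == "synonymous":
                        syn += 1
                    else:
                        nonsyn += 1
                    break

    return VariantSummary(
        snps_per_chromosome=snp_counts,
        indels_per_chromosome=indel_counts,
        mean_snps_per_chromosome=mean_per_chromosome(len(snps), len(lengths)),
        snp_frequency_bp_per_chromosome={
            name: snp_frequency_bp(lengths[name], n) for name, n in snp_counts.items() if n > 0
        },
        pi_per_chromosome={
            name: nucleotide_diversity(n, lengths[name]) for name, n in snp_counts.items()
        },
        ts_count=ts,
        tv_count=tv,
        subtype_counts=subtype_counts,
        indel_length_spectrum=indel_spectrum(indels),
        feature_counts=feature_counts,
        synonymous_count=syn,
        nonsynonymous_count=nonsyn,
    )
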