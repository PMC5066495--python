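"""Candidate-gene funnel: QTL intervals × differential expression.

Genes annotated inside a called QTL interval are intersected with
differentially expressed genes (DEGs: p < 0.05 and FDR < 0.05 between
the two parental genotypes) whose tissue and direction of change match
the interval's contributing parent.  For a negative interval (trait
allele from the B-inefficient parent) the required direction is W>Q —
higher transcript level in the B-inefficient genotype — and Q>W for a
positive interval; the default funnel keeps genes with that direction
in the roots but not in the shoots ("root-unique"), with a
both-tissues intersection mode available.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from bulkscan.qtlseq import QtlInterval
from bulkscan.variants import GeneModel

logger = logging.getLogger(__name__)

MODE_ROOT_UNIQUE = "root_unique"
MODE_ROOT_AND_SHOOT = "root_and_shoot"


@dataclass(frozen=True)
class DegRecord:
    """One per-gene, per-tissue expression comparison that passed the
    DEG thresholds."""

    gene_id: str
    tissue: str
    mean_q: float
    mean_w: float
    p: float
    fdr: float
    direction: str  # "Q>W" | "W>Q"


@dataclass(frozen=True)
class CandidateGene:
    """A gene surviving the interval × DEG funnel."""

    gene_id: str
    interval_id: str
    tissues_supporting: tuple[str, ...]
    direction: str
    rule: str


def adjust_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    table: pd.DataFrame,
    p_thresh: float = 0.05,
    fdr_thresh: float = 0.05,
) -> list[DegRecord]:
    """Apply the DEG definition: p < p_thresh AND fdr < fdr_thresh.

    The table needs columns gene_id, tissue, mean_q, mean_w, p (and
    optionally fdr; absent, BH-adjusted within tissue).  Rows with tied
    genotype means carry no direction and are excluded with a warning.
    """
    required = {"gene_id", "tissue", "mean_q", "mean_w", "p"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"expression table lacks columns: {sorted(missing)}")
    table = table.copy()
    if "fdr" not in table.columns:
        table["fdr"] = np.nan
        for tissue, idx in table.groupby("tissue").groups.items():
            table.loc[idx, "fdr"] = adjust_fdr(table.loc[idx, "p"].to_numpy())
    degs: list[DegRecord] = []
    n_ties = 0
    for row in table.itertuples(index=False):
        if not (row.p < p_thresh and row.fdr < fdr_thresh):
            continue
        if row.mean_q == row.mean_w:
            n_ties += 1
            continue
        degs.append(
            DegRecord(
                gene_id=row.gene_id,
                tissue=row.tissue,
                mean_q=float(row.mean_q),
                mean_w=float(row.mean_w),
                p=float(row.p),
                fdr=float(row.fdr),
                direction="Q>W" if row.mean_q > row.mean_w else "W>Q",
            )
        )
    if n_ties:
        warnings.warn(f"{n_ties} significant rows had tied genotype means; excluded")
    return degs


def genes_in_interval(
    interval: QtlInterval, genes: Sequence[GeneModel]
) -> list[GeneModel]:
    """Genes whose span overlaps the interval by at least 1 bp."""
    return [
        g
        for g in genes
        if g.chromosome == interval.chromosome
        and g.start <= interval.end
        and g.end >= interval.start
    ]


def required_direction(interval: QtlInterval) -> str:
    """Expression direction consistent with the interval's parent."""
    return "Q>W" if interval.sign == "+" else "W>Q"


def venn_filter(
    degs: Iterable[DegRecord],
    interval: QtlInterval,
    mode: str = MODE_ROOT_UNIQUE,
    genes: Sequence[GeneModel] | None = None,
) -> list[CandidateGene]:
    """Select candidate genes for one interval from its DEGs.

    ``degs`` should already be restricted to genes inside the interval;
    passing ``genes`` applies that restriction here.  ``root_unique``
    (default) keeps genes that are a root DEG in the required direction
    and *not* a shoot DEG in that direction; ``root_and_shoot`` requires
    the direction in both tissues.
    """
    if mode not in (MODE_ROOT_UNIQUE, MODE_ROOT_AND_SHOOT):
        raise ValueError(f"unknown mode {mode!r}")
    direction = required_direction(interval)
    if genes is not None:
        inside = {g.gene_id for g in genes_in_interval(interval, genes)}
        degs = [d for d in degs if d.gene_id in inside]
    by_gene: dict[str, dict[str, DegRecord]] = {}
    for d in degs:
        by_gene.setdefault(d.gene_id, {})[d.tissue] = d
    candidates: list[CandidateGene] = []
    for gene_id in sorted(by_gene):
        tissues = by_gene[gene_id]
        root_ok = "root" in tissues and tissues["root"].direction == direction
        shoot_ok = "shoot" in tissues and tissues["shoot"].direction == direction
        if mode == MODE_ROOT_UNIQUE:
            selected = root_ok and not shoot_ok
            supporting = ("root",)
            rule = f"root DEG {direction}, not a shoot DEG {direction}"
        else:
            selected = root_ok and shoot_ok
            supporting = ("root", "shoot")
            rule = f"DEG {direction} in both root and shoot"
        if selected:
            candidates.append(
                CandidateGene(
                    gene_id=gene_id,
                    interval_id=interval.interval_id,
                    tissues_supporting=supporting,
                    direction=direction,
                    rule=rule,
                )
            )
    return candidates


@dataclass
class FunnelReport:
    """Per-interval record of the candidate funnel."""

    interval_id: str
    n_genes_in_interval: int
    n_degs_in_interval: int
    n_candidates: int
    mode: str


def run_funnel(
    intervals: Sequence[QtlInterval],
    genes: Sequence[GeneModel],
    expression: pd.DataFrame,
    mode: str = MODE_ROOT_UNIQUE,
    p_thresh: float = 0.05,
    fdr_thresh: float = 0.05,
) -> tuple[dict[str, list[CandidateGene]], list[FunnelReport]]:
    """The full funnel for every interval: genes → DEGs → candidates."""
    degs = call_degs(expression, p_thresh=p_thresh, fdr_thresh=fdr_thresh)
    by_interval: dict[str, list[CandidateGene]] = {}
    reports: list[FunnelReport] = []
    for interval in intervals:
        inside = genes_in_interval(interval, genes)
        inside_ids = {g.gene_id for g in inside}
        local_degs = [d for d in degs if d.gene_id in inside_ids]
        cands = venn_filter(local_degs, interval, mode=mode)
        by_interval[interval.interval_id] = cands
        reports.append(
            FunnelReport(
                interval_id=interval.interval_id,
                n_genes_in_interval=len(inside),
                n_degs_in_interval=len({d.gene_id for d in local_degs}),
                n_candidates=len(cands),
                mode=mode,
            )
        )
        logger.info(
            "interval %s: %d genes, %d DEG genes, %d candidates",
            interval.interval_id, len(inside), len({d.gene_id for d in local_degs}),
            len(cands),
        )
    return by_interval, reports


def report_candidates(
    candidates_by_interval: dict[str, list[CandidateGene]],
    intervals: Sequence[QtlInterval],
    genes: Sequence[GeneModel],
    reports: Sequence[FunnelReport],
    outdir: str | Path,
    manifest_extra: dict | None = None,
) -> Path:
    """Write one candidate TSV per interval plus a JSON run manifest.

    Returns the manifest path.  Re-running with identical inputs yields
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_map = {g.gene_id: g for g in genes}
    for interval in intervals:
        path = outdir / f"candidates_{interval.interval_id}.tsv"
        with open(path, "w") as fh:
            fh.write("gene_id\tchromosome\tstart\tend\ttissues\tdirection\trule\n")
            for c in candidates_by_interval.get(interval.interval_id, []):
                g = gene_map[c.gene_id]
                fh.write(
                    f"{c.gene_id}\t{g.chromosome}\t{g.start}\t{g.end}\t"
                    f"{','.join(c.tissues_supporting)}\t{c.direction}\t{c.rule}\n"
                )
    manifest = {
        "funnel": [asdict(r) for r in reports],
        "intervals": [
            {
                "interval_id": iv.interval_id,
                "chromosome": iv.chromosome,
                "start": iv.start,
                "end": iv.end,
                "sign": iv.sign,
                "contributing_parent": iv.contributing_parent,
            }
            for iv in intervals
        ],
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    manifest_path = outdir / "candidates_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path
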