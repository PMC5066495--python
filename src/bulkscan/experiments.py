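"""Seeded calibration and recovery experiments.

Self-contained experiments that characterize the scan on synthetic
studies: null calibration (no planted locus → no called intervals),
parameter recovery (a strongly selected planted locus is found with the
right sign), end-to-end candidate recovery through the expression
funnel, and the sign-antisymmetry identity.  The test suite and the
acceptance script both drive these.

Study conditions: two 8-Mb chromosomes with markers every 10 kb, a
190-line DH population, bulks of the 22 phenotypic extremes, ~45x bulk
and ~18x parent depth, and (where planted) one locus whose allele
effect dwarfs the trait noise, emulating the design the package
targets at a desk-scale genome size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from bulkscan import pipeline, qtlseq, simdata
from bulkscan.config import PlantedQtl, ScanConfig, SimulationConfig

STUDY_CHROMS = {"A01": 8_000_000, "C02": 8_000_000}
QTL_CHROM = "C02"
QTL_POSITION = 4_000_000
QTL_EFFECT = 0.08  # grams per B-efficient-parent allele; >> trait noise spread
GENE_DENSITY = 25.0  # genes per Mb in the synthetic annotation


def _study_config(seed: int, effect: float | None = None) -> SimulationConfig:
    qtls = []
    if effect is not None:
        qtls = [PlantedQtl(QTL_CHROM, QTL_POSITION, effect, "planted")]
    return SimulationConfig(chrom_lengths=dict(STUDY_CHROMS), qtls=qtls, seed=seed)


def _scan_config(seed: int) -> ScanConfig:
    return ScanConfig(bulk_size=22, seed=seed)


def null_false_intervals(seed: int, n_genomes: int = 20) -> tuple[int, float]:
    """Scan ``n_genomes`` no-QTL studies; returns (total intervals called,
    max per-genome fraction of windows outside the 95% single-site band)."""
    total = 0
    max_frac = 0.0
    for i in range(n_genomes):
        study = pipeline.simulate_study(
            _study_config(seed + i), with_expression=False
        )
        res = pipeline.analyze_study(study, _scan_config(seed + i))
        total += len(res.intervals)
        band95 = qtlseq.null_band(22, 45, 0.95)[1]
        defined = [w for w in res.windows if not math.isnan(w.mean_delta)]
        if defined:
            outside = sum(1 for w in defined if abs(w.mean_delta) > band95)
            max_frac = max(max_frac, outside / len(defined))
    return total, max_frac


def qtl_recovery(seed: int, n_reps: int = 20, effect: float = QTL_EFFECT) -> int:
    """Count replicates whose scan yields exactly one interval on the
    planted chromosome, containing the planted position, with the sign
    of the planting (positive effect → B-efficient parent)."""
    expected_sign = "+" if effect > 0 else "-"
    successes = 0
    for i in range(n_reps):
        study = pipeline.simulate_study(
            _study_config(seed + 100 + i, effect=effect), with_expression=False
        )
        res = pipeline.analyze_study(study, _scan_config(seed + i))
        on_chrom = [iv for iv in res.intervals if iv.chromosome == QTL_CHROM]
        hits = [
            iv for iv in on_chrom
            if iv.start <= QTL_POSITION <= iv.end and iv.sign == expected_sign
        ]
        if len(on_chrom) == 1 and len(hits) == 1:
            successes += 1
    return successes


def candidate_recovery(seed: int, n_reps: int = 20) -> int:
    """End-to-end: plant a negative-effect locus plus one root-unique
    W>Q expression signal on a gene near it; count replicates where that
    gene is returned as the sole candidate."""
    successes = 0
    for i in range(n_reps):
        cfg = _study_config(seed + 200 + i, effect=-QTL_EFFECT)
        genes = simdata.generate_annotation(cfg.chrom_lengths, GENE_DENSITY, cfg.seed + 10)
        target = next(
            g for g in genes
            if g.chromosome == QTL_CHROM and abs(g.start - QTL_POSITION) < 2_000_000
        )
        study = pipeline.simulate_study(
            cfg,
            gene_density=GENE_DENSITY,
            planted_degs=[simdata.PlantedDeg(target.gene_id, ("root",), "W>Q", 8.0)],
        )
        res = pipeline.analyze_study(study, _scan_config(seed + i))
        cands = [c for lst in res.candidates.values() for c in lst]
        if len(cands) == 1 and cands[0].gene_id == target.gene_id:
            successes += 1
    return successes


@dataclass
class BandCheck:
    asymmetry: float  # |ci_low + ci_high| of the exact band
    mc_gap: float  # max abs difference MC vs exact, both bounds
    exact: tuple[float, float]


def band_calibration(seed: int, bulk_size: int = 22, depth: int = 45,
                     ci_level: float = 0.95, n_reps: int = 100_000) -> BandCheck:
    exact = qtlseq.null_band(bulk_size, depth, ci_level, mode="exact")
    mc = qtlseq.null_band(bulk_size, depth, ci_level, mode="mc",
                          n_reps=n_reps, seed=seed)
    return BandCheck(
        asymmetry=abs(exact[0] + exact[1]),
        mc_gap=max(abs(mc[0] - exact[0]), abs(mc[1] - exact[1])),
        exact=exact,
    )


def sign_antisymmetry(seed: int) -> tuple[float, bool]:
    """Swap the bulk columns of one planted study; returns the max
    |Δ_forward + Δ_swapped| over sites and whether every interval's
    contributing parent flipped."""
    study = pipeline.simulate_study(
        _study_config(seed + 300, effect=QTL_EFFECT), with_expression=False
    )
    fwd_cfg = _scan_config(seed)
    rev_cfg = ScanConfig(bulk_size=22, seed=seed,
                         bulk_be="bulk_BinE", bulk_bine="bulk_BE")
    fwd = qtlseq.scan(study.sites, fwd_cfg, study.config.chrom_lengths)
    rev = qtlseq.scan(study.sites, rev_cfg, study.config.chrom_lengths)
    max_err = max(
        (abs(a.delta + b.delta) for a, b in zip(fwd[0], rev[0])
         if not math.isnan(a.delta)),
        default=0.0,
    )
    flipped = (
        len(fwd[3]) == len(rev[3]) > 0
        and all(a.sign != b.sign and a.contributing_parent != b.contributing_parent
                for a, b in zip(fwd[3], rev[3]))
    )
    return max_err, flipped


def window_oracle_max_error(seed: int, n_fixtures: int = 10) -> float:
    """Max |implementation − brute force| window mean over random fixtures.

    The brute force recomputes every window mean by scanning the full
    site list, independent of the cumulative-sum implementation.
    """
    rng = np.random.default_rng(seed + 400)
    cfg = ScanConfig(bulk_size=22, window_size=5_000, step=1_000,
                     min_snps_per_window=2, min_depth=0, low_index_filter_on=False)
    worst = 0.0
    for _ in range(n_fixtures):
        length = int(rng.integers(8_000, 20_000))
        n = int(rng.integers(5, 60))
        positions = np.sort(rng.choice(np.arange(1, length + 1), size=n, replace=False))
        records = []
        for p in positions:
            d1, d2 = (int(x) for x in rng.integers(8, 60, size=2))
            a1 = int(rng.integers(0, d1 + 1))
            a2 = int(rng.integers(0, d2 + 1))
            records.append(
                qtlseq.SnpIndexRecord(
                    chromosome="A01", position=int(p), depth_be=d1, depth_bine=d2,
                    index_be=a1 / d1, index_bine=a2 / d2,
                    delta=a1 / d1 - a2 / d2,
                )
            )
        for w in qtlseq.sliding_window(records, cfg, {"A01": length}):
            inside = [r.delta for r in records if w.start <= r.position <= w.end]
            if len(inside) >= cfg.min_snps_per_window:
                worst = max(worst, abs(w.mean_delta - float(np.mean(inside))))
            else:
                assert math.isnan(w.mean_delta)
    return worst
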