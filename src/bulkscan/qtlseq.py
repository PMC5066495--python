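"""SNP-index / Δ(SNP-index) genome scan.

The core statistic of QTL-seq bulked-segregant analysis:

* SNP-index (per site, per bulk) = alternate-allele reads / total reads;
* Δ(SNP-index) = SNP-index(B-efficient bulk) − SNP-index(B-inefficient bulk);
* a sliding-window average (default 1 Mb window, 10 kb step) of Δ along
  each chromosome;
* a null confidence band for the doubled-haploid bulk design, computed by
  exact enumeration (or Monte Carlo) of the sampling distribution of Δ at
  an unlinked marker;
* interval calling: runs of consecutive same-sign windows exceeding the
  band merge into QTL intervals, whose sign names the contributing
  parent (Δ > 0: the B-efficient parent's allele raises the trait;
  Δ < 0: the B-inefficient parent's).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from bulkscan.config import ScanConfig
from bulkscan.variants import VariantSite

logger = logging.getLogger(__name__)

PARENT_BE = "BE-parent"
PARENT_BINE = "BinE-parent"


@dataclass
class SnpIndexRecord:
    """Per-site SNP-index values for the two bulks.

    ``index_be``/``index_bine``/``delta`` are NaN when the corresponding
    depth is zero.  Parent indices are carried when parent samples were
    present in the VCF, for the opposite-homozygote filter.
    """

    chromosome: str
    position: int
    depth_be: int
    depth_bine: int
    index_be: float
    index_bine: float
    delta: float
    index_parent_be: float = math.nan
    index_parent_bine: float = math.nan


def compute_snp_index(alt_count: int, total_count: int) -> float:
    """SNP-index = alternate reads / total reads; NaN when depth is 0."""
    if alt_count < 0 or total_count < 0:
        raise ValueError("read counts must be non-negative")
    if alt_count > total_count:
        raise ValueError(f"alt count {alt_count} exceeds total {total_count}")
    if total_count == 0:
        return math.nan
    return alt_count / total_count


def compute_delta(index_be: float, index_bine: float) -> float:
    """Δ(SNP-index); NaN propagates from either missing index."""
    return index_be - index_bine


def snp_index_records(
    sites: Sequence[VariantSite], config: ScanConfig
) -> list[SnpIndexRecord]:
    """Compute per-site SNP-index records from variant sites."""
    records: list[SnpIndexRecord] = []
    for site in sites:
        try:
            r_be, a_be = site.samples[config.bulk_be]
            r_bi, a_bi = site.samples[config.bulk_bine]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} absent at {site.chromosome}:{site.position}")
        idx_be = compute_snp_index(a_be, r_be + a_be)
        idx_bi = compute_snp_index(a_bi, r_bi + a_bi)
        rec = SnpIndexRecord(
            chromosome=site.chromosome,
            position=site.position,
            depth_be=r_be + a_be,
            depth_bine=r_bi + a_bi,
            index_be=idx_be,
            index_bine=idx_bi,
            delta=compute_delta(idx_be, idx_bi),
        )
        for attr, name in (
            ("index_parent_be", config.parent_be),
            ("index_parent_bine", config.parent_bine),
        ):
            if name and name in site.samples:
                r, a = site.samples[name]
                setattr(rec, attr, compute_snp_index(a, r + a))
        records.append(rec)
    return records


def filter_sites(
    records: Sequence[SnpIndexRecord], config: ScanConfig
) -> tuple[list[SnpIndexRecord], dict[str, int]]:
    """Apply the site-quality filters; returns (kept, drop counts per rule).

    Rules, in order: per-bulk depth below ``min_depth``; SNP-index below
    ``low_index_filter`` in *both* bulks (likely alignment artefacts);
    parent samples not opposite homozygotes (only when parent columns
    are present — a DH-population marker must separate the parents).
    """
    kept: list[SnpIndexRecord] = []
    dropped = {"depth": 0, "low_index_both_bulks": 0, "parents_not_opposite": 0}
    for rec in records:
        if rec.depth_be < config.min_depth or rec.depth_bine < config.min_depth:
            dropped["depth"] += 1
            continue
        if (
            config.low_index_filter_on
            and rec.index_be < config.low_index_filter
            and rec.index_bine < config.low_index_filter
        ):
            dropped["low_index_both_bulks"] += 1
            continue
        p_be, p_bi = rec.index_parent_be, rec.index_parent_bine
        if not math.isnan(p_be) and not math.isnan(p_bi):
            hom_alt = p_be >= 0.9
            hom_ref = p_bi <= 0.1
            if not (hom_alt and hom_ref):
                dropped["parents_not_opposite"] += 1
                continue
        kept.append(rec)
    for rule, n in dropped.items():
        logger.info("filter %s dropped %d sites", rule, n)
    return kept, dropped


@dataclass
class WindowStat:
    """One sliding-window record (1-based inclusive coordinates)."""

    chromosome: str
    start: int
    end: int
    mean_delta: float
    n_snps: int
    median_depth: int
    ci_low: float = math.nan
    ci_high: float = math.nan


def sliding_window(
    records: Sequence[SnpIndexRecord],
    config: ScanConfig,
    chrom_lengths: dict[str, int],
) -> list[WindowStat]:
    """Average Δ(SNP-index) in overlapping windows along each chromosome.

    Windows start at 1, 1+step, 1+2·step, … and span ``window_size`` bp
    (trailing windows truncated at the chromosome end).  Sites with a
    missing Δ are excluded from the mean; windows with fewer than
    ``min_snps_per_window`` contributing sites get a missing mean.  The
    per-window representative depth (for the null band) is the median
    over contributing sites of the mean per-bulk depth.
    """
    by_chrom: dict[str, list[SnpIndexRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chromosome, []).append(rec)
    windows: list[WindowStat] = []
    for chrom in chrom_lengths:
        recs = by_chrom.get(chrom, [])
        pos = np.array([r.position for r in recs], dtype=np.int64)
        if pos.size and np.any(np.diff(pos) < 0):
            raise ValueError(f"records on {chrom} are not sorted by position")
        delta = np.array([r.delta for r in recs], dtype=float)
        depth = np.array(
            [(r.depth_be + r.depth_bine) / 2.0 for r in recs], dtype=float
        )
        ok = ~np.isnan(delta)
        pos_ok, delta_ok, depth_ok = pos[ok], delta[ok], depth[ok]
        length = chrom_lengths[chrom]
        starts = np.arange(1, length + 1, config.step, dtype=np.int64)
        ends = np.minimum(starts + config.window_size - 1, length)
        lo = np.searchsorted(pos_ok, starts, side="left")
        hi = np.searchsorted(pos_ok, ends, side="right")
        csum = np.concatenate([[0.0], np.cumsum(delta_ok)])
        for s, e, i0, i1 in zip(starts, ends, lo, hi):
            n = int(i1 - i0)
            if n >= config.min_snps_per_window:
                mean = (csum[i1] - csum[i0]) / n
                med_depth = int(round(float(np.median(depth_ok[i0:i1]))))
            else:
                mean = math.nan
                med_depth = 0
            windows.append(
                WindowStat(
                    chromosome=chrom,
                    start=int(s),
                    end=int(e),
                    mean_delta=float(mean),
                    n_snps=n,
                    median_depth=max(med_depth, 1),
                )
            )
    return windows


# ---------------------------------------------------------------------------
# Null band
# ---------------------------------------------------------------------------

def _index_pmf(bulk_size: int, depth: int) -> np.ndarray:
    """Exact pmf of the bulk SNP-index on the grid 0/depth .. depth/depth.

    The bulk pools ``bulk_size`` homozygous DH lines, each carrying the
    ALT allele with probability 1/2 at an unlinked marker, so the true
    bulk allele frequency is k/bulk_size with k ~ Binomial(bulk_size, ½);
    ALT reads are then Binomial(depth, k/bulk_size).
    """
    k = np.arange(bulk_size + 1)
    pk = stats.binom.pmf(k, bulk_size, 0.5)
    a = np.arange(depth + 1)
    # (bulk_size+1, depth+1) lattice of read-count pmfs, mixed over k
    pa_given_k = stats.binom.pmf(a[None, :], depth, (k / bulk_size)[:, None])
    return pk @ pa_given_k


def null_band(
    bulk_size: int,
    depth: int,
    ci_level: float = 0.95,
    mode: str = "exact",
    n_reps: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Equal-tail null band for Δ(SNP-index) at an unlinked marker.

    ``mode="exact"`` enumerates the (bulk_size+1)×(depth+1) outcome
    lattice per bulk and convolves the two independent bulks;
    ``mode="mc"`` samples ``n_reps`` Monte-Carlo draws.  Returns
    (ci_low, ci_high): the lower band is the largest Δ with left-tail
    probability ≤ (1−ci_level)/2 and the upper band the smallest Δ with
    right-tail probability ≤ the same, each computed from its own tail
    so the symmetry of the null is a checkable property rather than an
    assumption.
    """
    if not 0.5 < ci_level < 1.0:
        raise ValueError(f"ci_level must lie in (0.5, 1), got {ci_level}")
    if bulk_size < 1 or depth < 1:
        raise ValueError("bulk_size and depth must be >= 1")
    alpha = 1.0 - ci_level
    support = np.arange(-depth, depth + 1) / depth
    if mode == "exact":
        pmf = _index_pmf(bulk_size, depth)
        # Δ support: (-depth .. depth)/depth; pmf of difference of two
        # independent indices = cross-correlation of the pmf with itself
        delta_pmf = np.convolve(pmf, pmf[::-1])
        return _equal_tail_band(support, delta_pmf, alpha)
    if mode == "mc":
        rng = np.random.default_rng(seed)
        k1 = rng.binomial(bulk_size, 0.5, size=n_reps)
        k2 = rng.binomial(bulk_size, 0.5, size=n_reps)
        a1 = rng.binomial(depth, k1 / bulk_size)
        a2 = rng.binomial(depth, k2 / bulk_size)
        counts = np.bincount(a1 - a2 + depth, minlength=2 * depth + 1)
        return _equal_tail_band(support, counts / n_reps, alpha)
    raise ValueError(f"unknown mode {mode!r}")


def _equal_tail_band(
    support: np.ndarray, pmf: np.ndarray, alpha: float
) -> tuple[float, float]:
    """Equal-tail band on a discrete Δ support.

    Lower bound: largest x with P(Δ ≤ x) ≤ α/2; upper bound: smallest x
    with P(Δ ≥ x) ≤ α/2.  Each tail is computed independently so the
    symmetry of a symmetric null is a property of the result, not an
    assumption of the code.
    """
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]
    lower_ok = np.nonzero(cdf <= alpha / 2 + 1e-12)[0]
    upper_ok = np.nonzero(sf <= alpha / 2 + 1e-12)[0]
    ci_low = float(support[lower_ok[-1]]) if lower_ok.size else float(support[0])
    ci_high = float(support[upper_ok[0]]) if upper_ok.size else float(support[-1])
    return ci_low, ci_high


def attach_null_bands(
    windows: Sequence[WindowStat], config: ScanConfig
) -> list[WindowStat]:
    """Fill each window's (ci_low, ci_high) at its representative depth.

    Bands are cached per distinct depth; with exact enumeration this is
    cheap even across many depths.
    """
    cache: dict[int, tuple[float, float]] = {}
    out: list[WindowStat] = []
    for w in windows:
        d = max(w.median_depth, 1)
        if d not in cache:
            if config.n_null_reps is None:
                cache[d] = null_band(config.bulk_size, d, config.ci_level, mode="exact")
            else:
                cache[d] = null_band(
                    config.bulk_size, d, config.ci_level,
                    mode="mc", n_reps=config.n_null_reps, seed=config.seed,
                )
        lo, hi = cache[d]
        out.append(replace(w, ci_low=lo, ci_high=hi))
    return out


# ---------------------------------------------------------------------------
# Interval calling
# ---------------------------------------------------------------------------

@dataclass
class QtlInterval:
    """A called QTL region.

    ``sign`` is "+" when the window means exceed the upper band (the
    B-efficient parent contributes the trait-raising allele) and "−"
    when they fall below the lower band (B-inefficient parent).
    """

    interval_id: str
    chromosome: str
    start: int
    end: int
    sign: str
    contributing_parent: str
    peak_delta: float
    n_windows: int

    def __post_init__(self) -> None:
        expected = PARENT_BE if self.sign == "+" else PARENT_BINE
        if self.contributing_parent != expected:
            raise ValueError(
                f"sign {self.sign} inconsistent with parent {self.contributing_parent}"
            )


def call_qtl_intervals(
    windows: Sequence[WindowStat], config: ScanConfig
) -> list[QtlInterval]:
    """Merge runs of significant same-sign windows into QTL intervals.

    A window is significant when its mean Δ lies outside its null band.
    Runs of at least ``min_consecutive_windows`` consecutive significant
    windows of one sign (windows overlap heavily at the default 1 Mb /
    10 kb geometry, so genuine QTLs produce long runs) are merged into
    one interval spanning their union.
    """
    if any(math.isnan(w.ci_high) for w in windows):
        windows = attach_null_bands(windows, config)
    by_chrom: dict[str, list[WindowStat]] = {}
    for w in windows:
        by_chrom.setdefault(w.chromosome, []).append(w)
    intervals: list[QtlInterval] = []
    counter = 0
    for chrom, ws in by_chrom.items():
        ws = sorted(ws, key=lambda w: w.start)
        run: list[tuple[WindowStat, int]] = []
        run_sign = 0

        def flush() -> None:
            nonlocal counter, run, run_sign
            if len(run) >= config.min_consecutive_windows:
                counter += 1
                stats_ = [w for w, _ in run]
                peak = max((w.mean_delta for w in stats_), key=abs)
                sign = "+" if run_sign > 0 else "-"
                intervals.append(
                    QtlInterval(
                        interval_id=f"qtl_{chrom}_{counter}",
                        chromosome=chrom,
                        start=min(w.start for w in stats_),
                        end=max(w.end for w in stats_),
                        sign=sign,
                        contributing_parent=PARENT_BE if sign == "+" else PARENT_BINE,
                        peak_delta=peak,
                        n_windows=len(stats_),
                    )
                )
            run, run_sign = [], 0

        for w in ws:
            if math.isnan(w.mean_delta):
                sig = 0
            elif w.mean_delta > w.ci_high:
                sig = 1
            elif w.mean_delta < w.ci_low:
                sig = -1
            else:
                sig = 0
            if sig == 0 or (run_sign and sig != run_sign):
                flush()
            if sig != 0:
                run.append((w, sig))
                run_sign = sig
        flush()
    intervals.sort(key=lambda iv: (iv.chromosome, iv.start))
    return intervals


def scan(
    sites: Sequence[VariantSite],
    config: ScanConfig,
    chrom_lengths: dict[str, int],
) -> tuple[list[SnpIndexRecord], dict[str, int], list[WindowStat], list[QtlInterval]]:
    """Full scan: indices → filters → windows → bands → intervals."""
    records = snp_index_records(sites, config)
    kept, dropped = filter_sites(records, config)
    windows = sliding_window(kept, config, chrom_lengths)
    windows = attach_null_bands(windows, config)
    intervals = call_qtl_intervals(windows, config)
    return kept, dropped, windows, intervals


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_site_table(records: Sequence[SnpIndexRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tposition\tdepth_be\tdepth_bine\tindex_be\tindex_bine\tdelta\n")
        for r in records:
            fh.write(
                f"{r.chromosome}\t{r.position}\t{r.depth_be}\t{r.depth_bine}\t"
                f"{r.index_be:.6g}\t{r.index_bine:.6g}\t{r.delta:.6g}\n"
            )


def write_window_table(windows: Sequence[WindowStat], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tstart\tend\tmean_delta\tn_snps\tmedian_depth\tci_low\tci_high\n")
        for w in windows:
            fh.write(
                f"{w.chromosome}\t{w.start}\t{w.end}\t{w.mean_delta:.6g}\t{w.n_snps}\t"
                f"{w.median_depth}\t{w.ci_low:.6g}\t{w.ci_high:.6g}\n"
            )


def write_intervals(
    intervals: Sequence[QtlInterval], bed_path: str | Path, tsv_path: str | Path
) -> None:
    """Write intervals as BED (0-based half-open) and annotated TSV."""
    with open(bed_path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chromosome}\t{iv.start - 1}\t{iv.end}\t{iv.interval_id}\n")
    with open(tsv_path, "w") as fh:
        fh.write(
            "interval_id\tchromosome\tstart\tend\tsign\tcontributing_parent\t"
            "peak_delta\tn_windows\n"
        )
        for iv in intervals:
            fh.write(
                f"{iv.interval_id}\t{iv.chromosome}\t{iv.start}\t{iv.end}\t{iv.sign}\t"
                f"{iv.contributing_parent}\t{iv.peak_delta:.6g}\t{iv.n_windows}\n"
            )


def read_intervals(tsv_path: str | Path) -> list[QtlInterval]:
    intervals = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            intervals.append(
                QtlInterval(
                    interval_id=row["interval_id"],
                    chromosome=row["chromosome"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    sign=row["sign"],
                    contributing_parent=row["contributing_parent"],
                    peak_delta=float(row["peak_delta"]),
                    n_windows=int(row["n_windows"]),
                )
            )
    return intervals


def plot_delta_profile(
    windows: Sequence[WindowStat],
    path: str | Path,
    intervals: Sequence[QtlInterval] = (),
) -> None:
    """Per-chromosome Δ(SNP-index) profile with the null band shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({w.chromosome for w in windows})
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 2.2 * len(chroms)), squeeze=False, sharey=True
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        ws = sorted((w for w in windows if w.chromosome == chrom), key=lambda w: w.start)
        mid = np.array([(w.start + w.end) / 2e6 for w in ws])
        mean = np.array([w.mean_delta for w in ws])
        lo = np.array([w.ci_low for w in ws])
        hi = np.array([w.ci_high for w in ws])
        ax.fill_between(mid, lo, hi, color="0.85", label="null band")
        ax.plot(mid, mean, lw=1.0, color="tab:blue")
        ax.axhline(0, color="0.5", lw=0.5)
        for iv in intervals:
            if iv.chromosome == chrom:
                ax.axvspan(iv.start / 1e6, iv.end / 1e6, color="tab:red", alpha=0.2)
        ax.set_ylabel("Δ(SNP-index)")
        ax.set_title(chrom, fontsize=9)
        ax.set_ylim(-1.05, 1.05)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
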