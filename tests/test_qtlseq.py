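"""Tests of the SNP-index statistic, windows, null band and calling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bulkscan import qtlseq
from bulkscan.config import ScanConfig
from bulkscan.qtlseq import (
    PARENT_BE,
    PARENT_BINE,
    SnpIndexRecord,
    WindowStat,
    call_qtl_intervals,
    compute_delta,
    compute_snp_index,
    filter_sites,
    null_band,
    sliding_window,
    snp_index_records,
)
from tests.conftest import make_site


class TestSnpIndex:
    @pytest.mark.parametrize(
        "alt,total,expected", [(0, 10, 0.0), (10, 10, 1.0), (18, 45, 0.4)]
    )
    def test_values(self, alt, total, expected):
        assert compute_snp_index(alt, total) == pytest.approx(expected)

    def test_zero_depth_is_missing(self):
        assert math.isnan(compute_snp_index(0, 0))

    def test_alt_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            compute_snp_index(11, 10)

    @given(st.integers(0, 500), st.integers(0, 500))
    def test_index_always_in_unit_interval(self, alt, extra):
        value = compute_snp_index(alt, alt + extra)
        if not math.isnan(value):
            assert 0.0 <= value <= 1.0


class TestDelta:
    @pytest.mark.parametrize(
        "be,bine,expected", [(1.0, 0.0, 1.0), (0.5, 0.5, 0.0), (0.2, 0.8, -0.6)]
    )
    def test_values(self, be, bine, expected):
        assert compute_delta(be, bine) == pytest.approx(expected)

    def test_missing_index_propagates(self):
        assert math.isnan(compute_delta(math.nan, 0.5))


def rec(pos, be=(10, 35), bine=(30, 15), chrom="A01", parents=None):
    site = make_site(chrom=chrom, pos=pos, be=be, bine=bine, parents=False)
    if parents:
        site.samples["parent_QY10"] = parents[0]
        site.samples["parent_W10"] = parents[1]
    cfg = ScanConfig(bulk_size=22)
    return snp_index_records([site], cfg)[0]


class TestFilters:
    def cfg(self, **kw):
        return ScanConfig(bulk_size=22, **kw)

    def test_low_depth_dropped(self):
        kept, dropped = filter_sites([rec(100, be=(3, 3), bine=(20, 25))], self.cfg())
        assert not kept and dropped["depth"] == 1

    def test_low_index_in_both_bulks_dropped(self):
        r = rec(100, be=(36, 4), bine=(32, 8))  # indices 0.1 and 0.2
        kept, dropped = filter_sites([r], self.cfg())
        assert not kept and dropped["low_index_both_bulks"] == 1

    def test_low_index_in_one_bulk_retained(self):
        r = rec(100, be=(36, 4), bine=(4, 36))  # 0.1 and 0.9
        kept, _ = filter_sites([r], self.cfg())
        assert len(kept) == 1

    def test_low_index_filter_can_be_disabled(self):
        r = rec(100, be=(36, 4), bine=(32, 8))
        kept, _ = filter_sites([r], self.cfg(low_index_filter_on=False))
        assert len(kept) == 1

    def test_non_opposite_parents_dropped(self):
        r = rec(100, parents=((9, 9), (18, 0)))  # first parent heterozygous-like
        kept, dropped = filter_sites([r], self.cfg())
        assert not kept and dropped["parents_not_opposite"] == 1

    def test_opposite_parents_retained(self):
        r = rec(100, parents=((0, 18), (18, 0)))
        kept, _ = filter_sites([r], self.cfg())
        assert len(kept) == 1


class TestSlidingWindow:
    def cfg(self, **kw):
        base = dict(bulk_size=22, window_size=1000, step=200, min_snps_per_window=1)
        base.update(kw)
        return ScanConfig(**base)

    def test_three_site_mean(self):
        # deltas 0.2, 0.4, 0.6 from chosen counts at depth 10
        recs = [
            rec(100, be=(4, 6), bine=(6, 4)),
            rec(200, be=(3, 7), bine=(7, 3)),
            rec(300, be=(2, 8), bine=(8, 2)),
        ]
        ws = sliding_window(recs, self.cfg(), {"A01": 1000})
        first = ws[0]
        assert first.n_snps == 3
        assert first.mean_delta == pytest.approx(0.4)

    def test_empty_window_missing(self):
        ws = sliding_window([rec(100)], self.cfg(), {"A01": 5000})
        far = [w for w in ws if w.start > 1200]
        assert all(math.isnan(w.mean_delta) for w in far)

    def test_single_site_identity(self):
        r = rec(500, be=(0, 45), bine=(45, 0))
        ws = sliding_window([r], self.cfg(), {"A01": 1000})
        assert ws[0].mean_delta == pytest.approx(1.0)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            sliding_window([rec(300), rec(100)], self.cfg(), {"A01": 1000})

    def test_windows_tile_from_one_with_step(self):
        ws = sliding_window([], self.cfg(min_snps_per_window=1), {"A01": 2500})
        starts = [w.start for w in ws]
        assert starts == [1, 201, 401, 601, 801, 1001, 1201, 1401, 1601, 1801,
                          2001, 2201, 2401]
        assert ws[-1].end == 2500

    def test_matches_bruteforce_on_random_fixtures(self):
        """Window means equal an independent brute-force recomputation on
        randomly generated site sets (the oracle ignores the cumulative-sum
        implementation entirely)."""
        rng = np.random.default_rng(123)
        cfg = self.cfg(window_size=5000, step=1000, min_snps_per_window=2)
        for _ in range(10):
            length = int(rng.integers(8_000, 20_000))
            n = int(rng.integers(5, 60))
            positions = np.sort(rng.choice(np.arange(1, length + 1), size=n, replace=False))
            recs = []
            for p in positions:
                d1, d2 = rng.integers(8, 60, size=2)
                a1, a2 = rng.integers(0, d1 + 1), rng.integers(0, d2 + 1)
                recs.append(rec(int(p), be=(int(d1 - a1), int(a1)),
                                bine=(int(d2 - a2), int(a2))))
            ws = sliding_window(recs, cfg, {"A01": length})
            for w in ws:
                inside = [r.delta for r in recs if w.start <= r.position <= w.end]
                if len(inside) >= cfg.min_snps_per_window:
                    assert w.mean_delta == pytest.approx(float(np.mean(inside)))
                    assert w.n_snps == len(inside)
                else:
                    assert math.isnan(w.mean_delta)


class TestNullBand:
    def test_symmetric_about_zero_exact(self):
        for depth in (7, 20, 45, 80):
            lo, hi = null_band(22, depth, 0.95, mode="exact")
            assert lo == pytest.approx(-hi)
            assert hi > 0

    def test_monte_carlo_close_to_exact(self):
        exact = null_band(22, 45, 0.95, mode="exact")
        mc = null_band(22, 45, 0.95, mode="mc", n_reps=100_000, seed=7)
        assert mc[0] == pytest.approx(exact[0], abs=0.02)
        assert mc[1] == pytest.approx(exact[1], abs=0.02)

    def test_band_shrinks_with_bulk_size_and_depth(self):
        small = null_band(22, 45)[1]
        large = null_band(500, 1000)[1]
        assert large < small
        assert large < 0.1  # half-width heads to 0 in the joint limit

    def test_wider_at_higher_confidence(self):
        assert null_band(22, 45, 0.99)[1] > null_band(22, 45, 0.95)[1]

    def test_invalid_ci_level_rejected(self):
        with pytest.raises(ValueError):
            null_band(22, 45, 1.5)


def make_windows(chrom, means, step=10, size=50, ci=0.4):
    ws = []
    for i, m in enumerate(means):
        start = 1 + i * step
        ws.append(
            WindowStat(chromosome=chrom, start=start, end=start + size - 1,
                       mean_delta=m, n_snps=20, median_depth=45,
                       ci_low=-ci, ci_high=ci)
        )
    return ws


class TestIntervalCalling:
    def cfg(self, **kw):
        base = dict(bulk_size=22, min_consecutive_windows=5, window_size=50, step=10,
                    min_snps_per_window=1)
        base.update(kw)
        return ScanConfig(**base)

    def test_all_within_band_no_intervals(self):
        ws = make_windows("A01", [0.1, -0.2, 0.0, 0.3, -0.1, 0.2, 0.1, 0.0])
        assert call_qtl_intervals(ws, self.cfg()) == []

    def test_positive_run_attributed_to_be_parent(self):
        ws = make_windows("A01", [0.0] * 3 + [0.8] * 10 + [0.0] * 3)
        ivs = call_qtl_intervals(ws, self.cfg())
        assert len(ivs) == 1
        assert ivs[0].sign == "+"
        assert ivs[0].contributing_parent == PARENT_BE
        assert ivs[0].peak_delta == pytest.approx(0.8)
        assert ivs[0].n_windows == 10

    def test_negative_run_attributed_to_bine_parent(self):
        ws = make_windows("A01", [0.0] * 3 + [-0.8] * 10 + [0.0] * 3)
        ivs = call_qtl_intervals(ws, self.cfg())
        assert len(ivs) == 1
        assert ivs[0].sign == "-"
        assert ivs[0].contributing_parent == PARENT_BINE

    def test_short_runs_not_called(self):
        ws = make_windows("A01", [0.0] * 3 + [0.8] * 4 + [0.0] * 3)
        assert call_qtl_intervals(ws, self.cfg()) == []

    def test_interval_spans_union_of_run_windows(self):
        ws = make_windows("A01", [0.0] * 2 + [0.9] * 6 + [0.0] * 2)
        iv = call_qtl_intervals(ws, self.cfg())[0]
        assert iv.start == 21 and iv.end == 21 + 5 * 10 + 50 - 1

    def test_sign_change_splits_runs(self):
        ws = make_windows("A01", [0.8] * 6 + [-0.8] * 6)
        ivs = call_qtl_intervals(ws, self.cfg())
        assert [iv.sign for iv in ivs] == ["+", "-"]


class TestSignAntisymmetry:
    def test_swapping_bulks_negates_deltas_and_flips_parents(self, small_sim_config):
        """Exchanging the two bulk columns must negate every Δ and flip
        every called interval's contributing parent."""
        from bulkscan import pipeline

        study = pipeline.simulate_study(small_sim_config, with_expression=False)
        fwd_cfg = ScanConfig(bulk_size=22)
        rev_cfg = ScanConfig(bulk_size=22, bulk_be="bulk_BinE", bulk_bine="bulk_BE")
        fwd = qtlseq.scan(study.sites, fwd_cfg, small_sim_config.chrom_lengths)
        rev = qtlseq.scan(study.sites, rev_cfg, small_sim_config.chrom_lengths)
        for a, b in zip(fwd[0], rev[0]):
            assert a.delta == pytest.approx(-b.delta, abs=1e-12)
        assert len(fwd[3]) == len(rev[3]) >= 1
        for ia, ib in zip(fwd[3], rev[3]):
            assert ia.sign != ib.sign
            assert {ia.contributing_parent, ib.contributing_parent} == {
                PARENT_BE, PARENT_BINE,
            }


class TestOutputs:
    def test_tables_and_bed_round_trip(self, tmp_path, small_sim_config, scan_config):
        from bulkscan import pipeline

        study = pipeline.simulate_study(small_sim_config, with_expression=False)
        records, _, windows, intervals = qtlseq.scan(
            study.sites, scan_config, small_sim_config.chrom_lengths
        )
        qtlseq.write_site_table(records, tmp_path / "sites.tsv")
        qtlseq.write_window_table(windows, tmp_path / "windows.tsv")
        qtlseq.write_intervals(intervals, tmp_path / "iv.bed", tmp_path / "iv.tsv")
        back = qtlseq.read_intervals(tmp_path / "iv.tsv")
        for a, b in zip(back, intervals):
            assert (a.interval_id, a.chromosome, a.start, a.end, a.sign,
                    a.contributing_parent, a.n_windows) == (
                b.interval_id, b.chromosome, b.start, b.end, b.sign,
                b.contributing_parent, b.n_windows)
            assert a.peak_delta == pytest.approx(b.peak_delta, abs=1e-5)
        bed_line = (tmp_path / "iv.bed").read_text().splitlines()[0].split("\t")
        assert int(bed_line[1]) == intervals[0].start - 1  # 0-based half-open
        assert int(bed_line[2]) == intervals[0].end
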