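"""SNP-index arithmetic, window means, null CIs, region calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyroqtl.qtlseq import (
    CandidateRegion,
    NullDeltaCI,
    attach_ci,
    call_regions,
    delta_index,
    intersect_pool_pairs,
    region_length,
    sliding_window_means,
    snp_index,
    total_span_mb,
)


class TestIndexArithmetic:
    @pytest.mark.parametrize(
        "alt,total,expected",
        [(0, 10, 0.0), (10, 10, 1.0), (3, 12, 0.25)],
    )
    def test_snp_index(self, alt, total, expected):
        assert snp_index(alt, total) == expected

    def test_zero_depth_undefined(self):
        with pytest.raises(ValueError, match="total_reads == 0"):
            snp_index(0, 0)

    @pytest.mark.parametrize(
        "rt,wt,expected", [(0.5, 0.5, 0.0), (1.0, 0.0, 1.0), (0.3, 0.7, -0.4)]
    )
    def test_delta_index(self, rt, wt, expected):
        assert delta_index(rt, wt) == pytest.approx(expected)

    def test_delta_bounds_checked(self):
        with pytest.raises(ValueError):
            delta_index(1.2, 0.0)


def make_table(chrom, positions, deltas, depth=100):
    n = len(positions)
    return pd.DataFrame({
        "chrom": [chrom] * n, "pos": positions,
        "depth_rt": [depth] * n, "depth_wt": [depth] * n,
        "index_rt": np.clip(deltas, 0, 1), "index_wt": [0.0] * n,
        "delta": deltas,
    })


class TestSlidingWindows:
    @given(st.lists(st.tuples(st.integers(1, 3_000_000),
                              st.floats(-1, 1, allow_nan=False)),
                    min_size=3, max_size=60))
    @settings(max_examples=30)
    def test_window_means_match_bruteforce(self, sites):
        sites = sorted({p: d for p, d in sites}.items())
        table = make_table("chr1", [p for p, _ in sites], [d for _, d in sites])
        win = sliding_window_means(table, {"chr1": 3_000_000}, window=1_000_000,
                                   step=500_000, min_snps=1)
        for _, w in win.iterrows():
            member = [d for p, d in sites if w["start"] <= p <= w["end"]]
            if member:
                assert w["mean_delta"] == pytest.approx(np.mean(member))
            else:
                assert np.isnan(w["mean_delta"])

    def test_boundary_site_inclusive(self):
        table = make_table("chr1", [1_000_000, 1_000_001], [1.0, -1.0])
        win = sliding_window_means(table, {"chr1": 2_000_000}, min_snps=1)
        first = win.iloc[0]
        assert first["start"] == 1 and first["end"] == 1_000_000
        assert first["mean_delta"] == 1.0  # site at exactly the window end

    def test_all_zero_deltas_give_zero_means(self):
        positions = list(range(1000, 900_000, 5000))
        table = make_table("chr1", positions, [0.0] * len(positions))
        win = sliding_window_means(table, {"chr1": 1_000_000})
        assert (win["mean_delta"].dropna() == 0).all()

    def test_window_grid_anchored_at_one(self):
        table = make_table("chr1", [5], [0.0])
        win = sliding_window_means(table, {"chr1": 350_000}, window=200_000,
                                   step=100_000, min_snps=1)
        assert list(win["start"]) == [1, 100_001, 200_001, 300_001]
        assert list(win["end"]) == [200_000, 300_000, 350_000, 350_000]

    def test_sparse_window_flagged_missing(self):
        table = make_table("chr1", [10, 20], [1.0, 1.0])
        win = sliding_window_means(table, {"chr1": 500_000}, window=500_000,
                                   step=100_000, min_snps=3)
        assert win["n_snps"].iloc[0] == 2
        assert np.isnan(win["mean_delta"].iloc[0])

    def test_window_smaller_than_step_rejected(self):
        table = make_table("chr1", [10], [0.0])
        with pytest.raises(ValueError, match="window"):
            sliding_window_means(table, {"chr1": 100}, window=10, step=20)
        with pytest.raises(ValueError, match="empty chromosome"):
            sliding_window_means(table, {}, window=100, step=100)


class TestNullCI:
    def test_degenerate_single_read_enumerable(self):
        # n=1, depth=1: each index is Bernoulli(1/2), delta in {-1,0,1} with
        # probabilities 1/4, 1/2, 1/4 -> the 95% bounds are the extremes
        ci = NullDeltaCI(n_rt=1, n_wt=1, replicates=10_000, seed=1)
        d = ci.draws(1, 1)
        assert set(np.unique(d)) <= {-1.0, 0.0, 1.0}
        freq = {v: (d == v).mean() for v in (-1.0, 0.0, 1.0)}
        assert freq[0.0] == pytest.approx(0.5, abs=0.02)
        assert freq[-1.0] == pytest.approx(0.25, abs=0.02)
        b = ci.bounds(1, 1)
        assert b[95] == (-1.0, 1.0) and b[99] == (-1.0, 1.0)

    def test_width_nonincreasing_in_depth_and_bulk_size(self):
        # grid of study-scale bulk sizes; at very small n the handful of
        # frequency atoms makes empirical quantiles non-monotone in depth
        widths = {}
        for n in (16, 24, 56):
            for depth in (10, 40, 160):
                ci = NullDeltaCI(n_rt=n, n_wt=n, replicates=10_000, seed=1)
                lo, hi = ci.bounds(depth, depth)[95]
                widths[(n, depth)] = hi - lo
        for n in (16, 24, 56):
            assert widths[(n, 10)] >= widths[(n, 40)] >= widths[(n, 160)]
        for depth in (10, 40, 160):
            assert widths[(16, depth)] >= widths[(24, depth)] >= widths[(56, depth)]

    def test_coverage_of_fresh_null_draws(self):
        # empirical 95% bounds should cover ~95% of new null draws
        ci = NullDeltaCI(n_rt=24, n_wt=24, replicates=10_000, seed=1)
        lo, hi = ci.bounds(100, 100)[95]
        fresh = ci.draws(100, 100, seed=999)
        coverage = ((fresh >= lo) & (fresh <= hi)).mean()
        assert coverage == pytest.approx(0.95, abs=0.01)

    def test_bounds_deterministic_and_cached(self):
        a = NullDeltaCI(8, 8, replicates=500, seed=3).bounds(30, 40)
        b = NullDeltaCI(8, 8, replicates=500, seed=3).bounds(30, 40)
        assert a == b

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            NullDeltaCI(4, 4, replicates=50)


class TestRegions:
    def window_frame(self, sig_starts, all_starts, chrom="chr1",
                     window=1_000_000):
        rows = []
        for s in all_starts:
            sig = s in sig_starts
            rows.append({"chrom": chrom, "start": s, "end": s + window - 1,
                         "n_snps": 10, "mean_delta": 0.8 if sig else 0.0,
                         "mean_hi95": 0.3, "mean_lo95": -0.3})
        return pd.DataFrame(rows)

    def test_no_significant_window_gives_empty_list(self):
        win = self.window_frame([], [1, 100_001])
        assert call_regions(win, 95) == []

    def test_contiguous_block_merges_to_printed_coordinates(self):
        # significant windows 39,700,001..42,000,001 (1-Mb span each) merge
        # into the single region 39,700,001-43,000,000
        starts = [i * 100_000 + 1 for i in range(390, 425)]
        sig = [i * 100_000 + 1 for i in range(397, 421)]
        win = self.window_frame(sig, starts)
        regions = call_regions(win, 95)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (39_700_001, 43_000_000)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            call_regions(self.window_frame([], [1]), level=80)

    def test_pool_pair_intersection_printed_coordinates(self):
        a = [CandidateRegion("chr1", 39_600_001, 43_200_000, 95, "RT24-WT24")]
        b = [CandidateRegion("chr1", 39_700_001, 43_000_000, 95, "RT56-WT56")]
        out = intersect_pool_pairs(a, b)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (39_700_001, 43_000_000)
        assert region_length(out[0]) == 3_300_000

    def test_disjoint_regions_intersect_empty(self):
        a = [CandidateRegion("chr1", 1, 100)]
        b = [CandidateRegion("chr1", 200, 300)]
        assert intersect_pool_pairs(a, b) == []
        c = [CandidateRegion("chr2", 1, 100)]
        assert intersect_pool_pairs(a, c) == []

    def test_intersection_idempotent_on_identical_inputs(self):
        a = [CandidateRegion("chr1", 10, 100), CandidateRegion("chr2", 5, 50)]
        out = intersect_pool_pairs(a, a)
        assert [(r.chrom, r.start, r.end) for r in out] == \
            [(r.chrom, r.start, r.end) for r in a]

    def test_total_span(self):
        regs = [CandidateRegion("chr1", 1, 1_000_000),
                CandidateRegion("chr3", 1, 300_000)]
        assert total_span_mb(regs) == pytest.approx(1.3)


class TestNullScan:
    def test_few_windows_significant_without_a_locus(self):
        # bulks drawn with no causal locus: every site's delta is a null
        # draw; window means compared against averaged per-site bounds
        # should flag at most ~5% of windows (in practice far fewer,
        # because averaging shrinks the window mean but not the bound)
        rng = np.random.default_rng(21)
        n, depth, n_sites = 24, 100, 4000
        pos = np.sort(rng.choice(20_000_000, size=n_sites, replace=False)) + 1
        idx = []
        for _ in range(2):
            counts = rng.binomial(n, 0.5, n_sites)
            idx.append(rng.binomial(depth, counts / n) / depth)
        table = pd.DataFrame({
            "chrom": "chr1", "pos": pos, "depth_rt": depth, "depth_wt": depth,
            "index_rt": idx[0], "index_wt": idx[1], "delta": idx[0] - idx[1],
        })
        ci = NullDeltaCI(n, n, replicates=2000, seed=1)
        table = attach_ci(table, ci)
        win = sliding_window_means(table, {"chr1": 20_000_000})
        regions = call_regions(win, 95)
        n_sig_windows = sum(
            ((win["chrom"] == r.chrom) & (win["start"] >= r.start)
             & (win["end"] <= r.end)).sum() for r in regions
        )
        assert n_sig_windows <= 0.05 * len(win)


class TestAttachCI:
    def test_per_site_bounds_keyed_by_depth_pair(self):
        table = make_table("chr1", [100, 200, 300], [0.0, 0.0, 0.0])
        table.loc[2, "depth_rt"] = 10
        ci = NullDeltaCI(8, 8, replicates=1000, seed=1)
        out = attach_ci(table, ci)
        assert set(out.columns) >= {"lo95", "hi95", "lo99", "hi99"}
        # identical depth pairs share bounds; the low-depth site is wider
        assert out.loc[0, "hi95"] == out.loc[1, "hi95"]
        assert out.loc[2, "hi95"] > out.loc[0, "hi95"]
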