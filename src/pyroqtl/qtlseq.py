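"""SNP-index / delta(SNP-index) scan with simulated null confidence intervals.

The core bulked-segregant statistic: for each parent-differentiating site, the
SNP-index of a bulk is the fraction of reads carrying the HT (paternal,
non-reference) allele, and delta = index(RT bulk) - index(WT bulk).  Near the
causal locus the RT bulk fixes the HT allele and the WT bulk the RZ allele, so
delta -> +1; elsewhere delta ~ 0.  Window means of delta are compared against
confidence bounds obtained by simulating the null (no QTL) twice-binomial
sampling process at the observed bulk sizes and read depths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_filter import VariantRecord

__all__ = [
    "snp_index",
    "delta_index",
    "snp_index_table",
    "NullDeltaCI",
    "attach_ci",
    "sliding_window_means",
    "CandidateRegion",
    "call_regions",
    "intersect_pool_pairs",
    "region_length",
    "total_span_mb",
]


def snp_index(alt_reads: int, total_reads: int) -> float:
    """Fraction of reads supporting the HT (alternate) allele."""
    if total_reads < 1:
        raise ValueError("snp_index undefined for total_reads == 0; filter the site")
    if not 0 <= alt_reads <= total_reads:
        raise ValueError("need 0 <= alt_reads <= total_reads")
    return alt_reads / total_reads


def delta_index(index_rt: float, index_wt: float) -> float:
    """delta(SNP-index) = index in the RT bulk minus index in the WT bulk."""
    for v in (index_rt, index_wt):
        if not 0.0 <= v <= 1.0:
            raise ValueError("indices must lie in [0, 1]")
    return index_rt - index_wt


def snp_index_table(
    records: Sequence[VariantRecord], rt_pool: str, wt_pool: str
) -> pd.DataFrame:
    """Per-site index/delta table for one bulk pair.

    Columns: chrom, pos, depth_rt, depth_wt, index_rt, index_wt, delta.
    """
    rows = []
    for rec in records:
        a_rt, d_rt = rec.pools[rt_pool]
        a_wt, d_wt = rec.pools[wt_pool]
        i_rt = snp_index(a_rt, d_rt)
        i_wt = snp_index(a_wt, d_wt)
        rows.append((rec.chrom, rec.pos, d_rt, d_wt, i_rt, i_wt, i_rt - i_wt))
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "depth_rt", "depth_wt", "index_rt", "index_wt", "delta"],
    )


# Process-wide cache of simulated bounds.  Bounds depend only on
# (n_rt, n_wt, depth_rt, depth_wt, replicates, seed); reusing them across
# runs changes nothing statistically and avoids re-simulating identical
# configurations.
_CI_CACHE: dict[tuple, dict[int, tuple[float, float]]] = {}


class NullDeltaCI:
    """Simulated null distribution of delta(SNP-index).

    Under the null (no QTL) each bulk of ``n`` haploid segregants carries the
    HT allele with frequency Binomial(n, 1/2)/n, and the observed index
    resamples that frequency with Binomial(depth, p_hat)/depth reads.  The
    delta bounds are symmetric two-sided empirical quantiles of
    ``replicates`` such draws.

    Each (depth_rt, depth_wt) pair gets its own reproducible stream derived
    from ``seed`` and the pair, so bounds are independent of the order in
    which pairs are requested.
    """

    def __init__(
        self,
        n_rt: int,
        n_wt: int,
        replicates: int = 10_000,
        seed: int = 1,
        levels: Sequence[int] = (95, 99),
    ) -> None:
        if min(n_rt, n_wt) < 1:
            raise ValueError("bulk sizes must be >= 1")
        if replicates < 100:
            raise ValueError("need at least 100 replicates")
        self.n_rt = int(n_rt)
        self.n_wt = int(n_wt)
        self.replicates = int(replicates)
        self.seed = int(seed)
        self.levels = tuple(int(l) for l in levels)

    def draws(self, depth_rt: int, depth_wt: int, seed: int | None = None) -> np.ndarray:
        """Null delta draws at the given read depths (fresh array each call)."""
        if min(depth_rt, depth_wt) < 1:
            raise ValueError("depths must be >= 1")
        rng = np.random.default_rng(
            [seed if seed is not None else self.seed,
             self.n_rt, self.n_wt, int(depth_rt), int(depth_wt)]
        )
        idx = []
        reps = self.replicates
        for n, depth in ((self.n_rt, depth_rt), (self.n_wt, depth_wt)):
            counts = rng.binomial(n, 0.5, reps)
            # group replicates sharing a bulk allele count: scalar-p binomial
            # sampling per group (same distribution, far fewer RNG calls)
            order = np.argsort(counts, kind="stable")
            vals, starts = np.unique(counts[order], return_index=True)
            ends = np.append(starts[1:], reps)
            reads_sorted = np.empty(reps)
            for v, s, e in zip(vals, starts, ends):
                reads_sorted[s:e] = rng.binomial(int(depth), v / n, size=int(e - s))
            reads = np.empty(reps)
            reads[order] = reads_sorted
            idx.append(reads / depth)
        return idx[0] - idx[1]

    def bounds(self, depth_rt: int, depth_wt: int) -> dict[int, tuple[float, float]]:
        """Two-sided empirical CI bounds keyed by level (e.g. 95 -> (lo, hi))."""
        key = (self.n_rt, self.n_wt, self.replicates, self.seed,
               int(depth_rt), int(depth_wt))
        cached = _CI_CACHE.get(key)
        if cached is not None:
            return cached
        d = self.draws(depth_rt, depth_wt)
        probs = []
        for level in self.levels:
            tail = (100 - level) / 200
            probs += [tail, 1 - tail]
        qs = np.quantile(d, probs)
        out = {level: (float(qs[2 * i]), float(qs[2 * i + 1]))
               for i, level in enumerate(self.levels)}
        _CI_CACHE[key] = out
        return out


def attach_ci(table: pd.DataFrame, ci: NullDeltaCI) -> pd.DataFrame:
    """Add per-site null CI bound columns (lo95/hi95/lo99/hi99, per level).

    Bounds are keyed by each site's observed (depth_rt, depth_wt); identical
    pairs share one simulation.
    """
    pairs = table[["depth_rt", "depth_wt"]].to_numpy(int)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    cols = {f"{side}{lvl}": np.empty(len(uniq)) for lvl in ci.levels for side in ("lo", "hi")}
    for i, (d_rt, d_wt) in enumerate(uniq):
        b = ci.bounds(int(d_rt), int(d_wt))
        for lvl in ci.levels:
            cols[f"lo{lvl}"][i] = b[lvl][0]
            cols[f"hi{lvl}"][i] = b[lvl][1]
    out = table.copy()
    for name, vals in cols.items():
        out[name] = vals[inverse]
    return out


def sliding_window_means(
    table: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window: int = 1_000_000,
    step: int = 100_000,
    min_snps: int = 3,
) -> pd.DataFrame:
    """Window means of delta (and of any attached CI bounds).

    Windows are anchored at 1, step+1, 2*step+1, ... and span ``window`` bp
    (1-based inclusive; the last windows truncate at the chromosome end).  A
    site at exactly the window end is included.  Windows with fewer than
    ``min_snps`` sites are reported with NaN means (flagged missing).
    """
    if window < step:
        raise ValueError("window must be >= step")
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    if not chrom_lengths:
        raise ValueError("empty chromosome set")

    mean_cols = ["delta"] + [c for c in table.columns if c.startswith(("lo", "hi"))]
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = table[table["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy()
        csums = {c: np.concatenate([[0.0], np.cumsum(sub[c].to_numpy(float))])
                 for c in mean_cols}
        starts = np.arange(1, int(length) + 1, step)
        ends = np.minimum(starts + window - 1, int(length))
        left = np.searchsorted(pos, starts, side="left")
        right = np.searchsorted(pos, ends, side="right")
        n = right - left
        for s, e, l, r, cnt in zip(starts, ends, left, right, n):
            row = {"chrom": chrom, "start": int(s), "end": int(e), "n_snps": int(cnt)}
            for c in mean_cols:
                key = "mean_" + c if c == "delta" else "mean_" + c
                row[key] = (csums[c][r] - csums[c][l]) / cnt if cnt >= min_snps else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True, order=True)
class CandidateRegion:
    """1-based inclusive genomic interval called from the window scan."""

    chrom: str
    start: int
    end: int
    level: int = 95
    source: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end in {self}")


def region_length(region: CandidateRegion) -> int:
    """Interval length in bp, 1-based inclusive (end - start + 1)."""
    return region.end - region.start + 1


def total_span_mb(regions: Iterable[CandidateRegion]) -> float:
    """Total length of a region list, in Mb."""
    return sum(region_length(r) for r in regions) / 1e6


def call_regions(
    windows: pd.DataFrame, level: int = 95, source: str = ""
) -> list[CandidateRegion]:
    """Merge significant windows into maximal candidate regions.

    A window is significant when its mean delta exceeds its mean upper CI
    bound at ``level`` — one-sided toward positive delta, because the RT-WT
    contrast drives the causal signal upward by construction.  Overlapping or
    abutting significant windows merge; a region spans from the first
    window's start to the last window's end.
    """
    col = f"mean_hi{level}"
    if col not in windows.columns:
        raise ValueError(f"significance level {level} not available (no column {col})")
    regions: list[CandidateRegion] = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur: list[int] | None = None
        for _, w in sub.iterrows():
            sig = (
                w["n_snps"] > 0
                and np.isfinite(w["mean_delta"])
                and np.isfinite(w[col])
                and w["mean_delta"] > w[col]
            )
            if sig:
                if cur is not None and w["start"] <= cur[1] + 1:
                    cur[1] = max(cur[1], int(w["end"]))
                else:
                    if cur is not None:
                        regions.append(CandidateRegion(chrom, cur[0], cur[1], level, source))
                    cur = [int(w["start"]), int(w["end"])]
        if cur is not None:
            regions.append(CandidateRegion(chrom, cur[0], cur[1], level, source))
    return regions


def intersect_pool_pairs(
    regions_a: Sequence[CandidateRegion], regions_b: Sequence[CandidateRegion]
) -> list[CandidateRegion]:
    """Interval intersection of two region lists (1-based inclusive).

    Each input list must be internally disjoint; the result carries the
    sources of both parents joined with '&'.
    """
    out: list[CandidateRegion] = []
    for a in sorted(regions_a):
        for b in sorted(regions_b):
            if a.chrom != b.chrom:
                continue
            lo, hi = max(a.start, b.start), min(a.end, b.end)
            if lo <= hi:
                source = "&".join(s for s in (a.source, b.source) if s) or ""
                out.append(CandidateRegion(a.chrom, lo, hi, min(a.level, b.level), source))
    return sorted(out)


def plot_delta(windows: pd.DataFrame, path: str, level: int = 95) -> None:
    """Per-chromosome delta(SNP-index) plot with CI bands (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(windows["chrom"]))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(9, 2.6 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes.ravel(), chroms):
        sub = windows[windows["chrom"] == chrom]
        mid = (sub["start"] + sub["end"]) / 2e6
        ax.plot(mid, sub["mean_delta"], color="black", lw=1)
        for lvl, color in ((95, "tab:blue"), (99, "tab:red")):
            for side in ("lo", "hi"):
                col = f"mean_{side}{lvl}"
                if col in sub.columns:
                    ax.plot(mid, sub[col], color=color, lw=0.8, ls="--")
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_ylabel("delta(SNP-index)")
        ax.set_title(chrom)
        ax.set_ylim(-1.05, 1.05)
    axes.ravel()[-1].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
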