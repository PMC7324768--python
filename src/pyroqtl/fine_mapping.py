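"""Segregation test, marker binning, haploid LOD scan, recombinant narrowing.

These are the confirmation / narrowing steps that follow the genome-wide
bulk scan: a goodness-of-fit test for 1:1 phenotype segregation, clustering
of cosegregating markers into bin markers, a single-marker binomial
likelihood LOD scan with a permutation threshold for a binary trait in a
haploid mapping population, and interval narrowing from recombinants scored
at individual (KASP-style) markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .qtlseq import CandidateRegion

__all__ = [
    "SegregationTest",
    "chi_square_segregation",
    "GenotypeMatrix",
    "BinResult",
    "screen_and_bin_markers",
    "lod_scores",
    "QtlPeak",
    "LodScanResult",
    "lod_scan",
    "NarrowResult",
    "narrow_by_recombinants",
    "average_marker_spacing_cm",
]

#: chi-square critical value at alpha=0.05, df=1
CHI2_CRITICAL_05 = float(stats.chi2.isf(0.05, df=1))

# missing genotype code in integer matrices
MISSING = -1


@dataclass(frozen=True)
class SegregationTest:
    chi2: float
    critical: float
    significant: bool


def chi_square_segregation(count_wt: int, count_rt: int) -> SegregationTest:
    """Goodness-of-fit chi-square against a 1:1 WT:RT ratio (df=1).

    Uncorrected (no Yates continuity correction): chi2 = sum (O-E)^2 / E with
    E = total/2.  ``significant`` means departure from 1:1 at alpha = 0.05.
    """
    if min(count_wt, count_rt) < 0:
        raise ValueError("counts must be >= 0")
    total = count_wt + count_rt
    if total == 0:
        raise ValueError("both counts are zero")
    expected = total / 2
    chi2 = (count_wt - expected) ** 2 / expected + (count_rt - expected) ** 2 / expected
    return SegregationTest(chi2=float(chi2), critical=CHI2_CRITICAL_05,
                           significant=chi2 > CHI2_CRITICAL_05)


@dataclass
class GenotypeMatrix:
    """Samples x markers haploid genotype matrix.

    ``genotypes`` holds 0 (RZ allele), 1 (HT allele) or -1 (missing).
    ``markers`` has columns ``id``, ``chrom``, ``pos`` (bp) and optionally
    ``cm``; rows must be sorted by (chrom, pos).  ``phenotypes`` holds 0 (WT)
    or 1 (RT) per sample.
    """

    genotypes: np.ndarray
    markers: pd.DataFrame
    phenotypes: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotypes = np.asarray(self.phenotypes, dtype=np.int8)
        n_s, n_m = self.genotypes.shape
        if len(self.markers) != n_m:
            raise ValueError("marker table does not match genotype columns")
        if len(self.phenotypes) != n_s:
            raise ValueError("phenotypes do not match genotype rows")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(n_s)]
        for _, sub in self.markers.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError("markers must be sorted by (chrom, pos)")

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.genotypes[:, idx],
            self.markers.iloc[idx].reset_index(drop=True),
            self.phenotypes,
            list(self.sample_ids),
        )


@dataclass
class BinResult:
    """Marker screening + binning outcome.

    ``representatives`` indexes the screened matrix; ``bins`` maps each
    representative marker id to the ids of all members of its bin (identical
    genotype vectors, missing treated as its own symbol).
    """

    matrix: GenotypeMatrix          # screened matrix restricted to representatives
    bins: dict[str, list[str]]
    n_removed_missing: int
    n_removed_maf: int


def screen_and_bin_markers(
    gm: GenotypeMatrix, max_missing: float = 0.2, min_maf: float = 0.05
) -> BinResult:
    """Drop low-quality markers, then cluster cosegregating ones into bins.

    Markers are removed when the missing rate exceeds ``max_missing`` or the
    minor-allele frequency (among non-missing calls) falls below ``min_maf``.
    Surviving markers with exactly equal genotype vectors form one bin whose
    representative is the leftmost member by position.
    """
    g = gm.genotypes
    n_s = g.shape[0]
    missing = (g == MISSING).sum(axis=0) / n_s
    informative = (g != MISSING).sum(axis=0)
    ht = (g == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(informative > 0, ht / np.maximum(informative, 1), np.nan)
    maf = np.minimum(freq, 1 - freq)

    pass_missing = missing <= max_missing
    pass_maf = pass_missing & (maf >= min_maf)
    n_removed_missing = int((~pass_missing).sum())
    n_removed_maf = int((pass_missing & ~pass_maf).sum())
    keep = np.flatnonzero(pass_maf)
    if keep.size == 0:
        raise ValueError("all markers removed by screening filters")

    screened = gm.subset_markers(keep)
    cols = screened.genotypes.T  # markers x samples
    _, inverse = np.unique(cols, axis=0, return_inverse=True)
    bins: dict[str, list[str]] = {}
    rep_idx: list[int] = []
    first_of_group: dict[int, int] = {}
    ids = screened.markers["id"].tolist()
    for j, grp in enumerate(inverse):
        if grp not in first_of_group:
            first_of_group[grp] = j
            rep_idx.append(j)
            bins[ids[j]] = [ids[j]]
        else:
            bins[ids[first_of_group[grp]]].append(ids[j])
    rep = np.array(sorted(rep_idx))
    return BinResult(
        matrix=screened.subset_markers(rep),
        bins=bins,
        n_removed_missing=n_removed_missing,
        n_removed_maf=n_removed_maf,
    )


def lod_scores(genotypes: np.ndarray, phenotypes: np.ndarray) -> np.ndarray:
    """Single-marker LOD for a binary trait in haploids.

    With r recombinants (allele differing from the phenotype-implied allele,
    RT=>HT, WT=>RZ) among n informative samples, theta_hat = r/n and

        LOD = log10[ theta_hat^r (1-theta_hat)^(n-r) / 0.5^n ]

    with the 0^0 = 1 convention.  Missing genotypes are excluded from r and n.
    """
    g = np.asarray(genotypes)
    p = np.asarray(phenotypes).reshape(-1, 1)
    valid = g != MISSING
    rec = valid & (g != p)
    r = rec.sum(axis=0).astype(float)
    n = valid.sum(axis=0).astype(float)
    return _lod_from_counts(r, n)


def _lod_from_counts(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(n > 0, r / np.maximum(n, 1), np.nan)
        term_r = np.where(r > 0, r * np.log10(theta), 0.0)
        term_nr = np.where(n - r > 0, (n - r) * np.log10(1 - theta), 0.0)
    lod = term_r + term_nr + n * np.log10(2.0)
    return np.where(n > 0, lod, np.nan)


@dataclass(frozen=True)
class QtlPeak:
    marker_id: str
    chrom: str
    pos: int
    cm: float
    lod: float
    threshold: float
    support_cm: tuple[float, float]
    support_bp: tuple[int, int]


@dataclass
class LodScanResult:
    lod: np.ndarray
    threshold: float
    peaks: list[QtlPeak]
    cm: np.ndarray


def _genetic_positions(markers: pd.DataFrame, cm_per_mb: float) -> np.ndarray:
    if "cm" in markers.columns and markers["cm"].notna().all():
        return markers["cm"].to_numpy(float)
    return markers["pos"].to_numpy(float) / 1e6 * cm_per_mb


def lod_scan(
    gm: GenotypeMatrix,
    permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 1,
    cm_per_mb: float = 4.37,
    merge_cm: float = 10.0,
    lod_drop: float = 1.5,
) -> LodScanResult:
    """Genome scan with a permutation-derived significance threshold.

    The threshold is the (1-alpha) quantile of the maximum LOD over markers
    under ``permutations`` random phenotype relabelings.  Contiguous
    above-threshold runs form QTLs; peaks of adjacent QTLs closer than
    ``merge_cm`` centimorgans are merged keeping the higher peak; each peak's
    support interval is the contiguous run of markers within ``lod_drop`` of
    the peak LOD.  When no cM map is supplied, physical positions are
    converted with ``cm_per_mb`` (used for the merge rule only).
    """
    g = gm.genotypes
    p = gm.phenotypes
    if len(np.unique(p)) < 2:
        raise ValueError("need both phenotype classes present")
    if g.shape[0] < 2:
        raise ValueError("need at least two samples")
    valid = (g != MISSING)
    if (valid.sum(axis=0) == 0).any():
        raise ValueError("all-missing marker in genotype matrix")

    lod = lod_scores(g, p)
    cm = _genetic_positions(gm.markers, cm_per_mb)

    # permutation null of max LOD: recombinant counts via matrix products
    rng = np.random.default_rng(seed)
    V = valid.astype(np.float32)
    A = (valid & (g == 1)).astype(np.float32)
    col_a = A.sum(axis=0)
    n = V.sum(axis=0)
    max_lods = np.empty(permutations)
    chunk = 250
    for start in range(0, permutations, chunk):
        k = min(chunk, permutations - start)
        P = np.stack([rng.permutation(p).astype(np.float32) for _ in range(k)])
        r = col_a + P @ V - 2.0 * (P @ A)  # mismatches per marker per permutation
        lods = _lod_from_counts(r, np.broadcast_to(n, r.shape))
        max_lods[start:start + k] = np.nanmax(lods, axis=1)
    threshold = float(np.quantile(max_lods, 1 - alpha))

    peaks = _call_peaks(gm.markers, lod, cm, threshold, merge_cm, lod_drop)
    return LodScanResult(lod=lod, threshold=threshold, peaks=peaks, cm=cm)


def _call_peaks(
    markers: pd.DataFrame,
    lod: np.ndarray,
    cm: np.ndarray,
    threshold: float,
    merge_cm: float,
    lod_drop: float,
) -> list[QtlPeak]:
    peaks: list[QtlPeak] = []
    chroms = markers["chrom"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        above = lod[idx] > threshold
        # contiguous above-threshold runs -> candidate peaks
        run_peaks: list[int] = []
        start = None
        for j, flag in enumerate(above):
            if flag and start is None:
                start = j
            if (not flag or j == len(above) - 1) and start is not None:
                stop = j if not flag else j + 1
                run = idx[start:stop]
                run_peaks.append(run[np.argmax(lod[run])])
                start = None
        # merge peaks closer than merge_cm, keeping the higher
        merged: list[int] = []
        for pk in sorted(run_peaks, key=lambda i: cm[i]):
            if merged and cm[pk] - cm[merged[-1]] < merge_cm:
                if lod[pk] > lod[merged[-1]]:
                    merged[-1] = pk
            else:
                merged.append(pk)
        for pk in merged:
            lo = hi = int(np.flatnonzero(idx == pk)[0])
            within = lod[idx] >= lod[pk] - lod_drop
            while lo > 0 and within[lo - 1]:
                lo -= 1
            while hi < len(idx) - 1 and within[hi + 1]:
                hi += 1
            i_lo, i_hi = idx[lo], idx[hi]
            peaks.append(
                QtlPeak(
                    marker_id=str(markers["id"].iloc[pk]),
                    chrom=str(chrom),
                    pos=int(markers["pos"].iloc[pk]),
                    cm=float(cm[pk]),
                    lod=float(lod[pk]),
                    threshold=threshold,
                    support_cm=(float(cm[i_lo]), float(cm[i_hi])),
                    support_bp=(int(markers["pos"].iloc[i_lo]), int(markers["pos"].iloc[i_hi])),
                )
            )
    return sorted(peaks, key=lambda q: -q.lod)


@dataclass
class NarrowResult:
    region: CandidateRegion
    recombinants: dict[str, list[str]]   # marker id -> recombinant sample ids
    cosegregating: list[str]             # marker ids with zero recombinants


def narrow_by_recombinants(
    markers: pd.DataFrame,
    genotypes: np.ndarray,
    phenotypes: np.ndarray,
    sample_ids: Sequence[str],
    prior: CandidateRegion,
) -> NarrowResult:
    """Narrow a candidate interval using recombinants at individual markers.

    A sample is recombinant at a marker when its allele differs from the
    phenotype-implied allele (RT => HT, WT => RZ; missing calls are skipped).
    Markers with zero recombinants cosegregate with the locus, so the locus
    must lie between the recombinant-bearing markers flanking the
    cosegregating block: the new boundary on each side is the innermost such
    marker's position (the boundary marker itself stays inside the region).
    A side with no recombinant-bearing marker keeps the prior boundary; with
    no cosegregating marker at all the prior region is returned unchanged.
    """
    pos = markers["pos"].to_numpy(int)
    if not np.all(np.diff(pos) > 0):
        raise ValueError("markers must be strictly ordered by position")
    g = np.asarray(genotypes, dtype=np.int8)
    p = np.asarray(phenotypes, dtype=np.int8)
    if np.any(p == MISSING):
        raise ValueError("phenotype missing for a genotyped sample")

    valid = g != MISSING
    rec = valid & (g != p.reshape(-1, 1))
    ids = [str(i) for i in markers["id"]]
    recombinants = {
        ids[j]: [str(sample_ids[i]) for i in np.flatnonzero(rec[:, j])]
        for j in range(len(ids))
    }
    coseg_idx = [j for j in range(len(ids)) if not recombinants[ids[j]]]
    cosegregating = [ids[j] for j in coseg_idx]
    if not coseg_idx:
        return NarrowResult(region=prior, recombinants=recombinants,
                            cosegregating=cosegregating)

    lo_c, hi_c = pos[coseg_idx[0]], pos[coseg_idx[-1]]
    left = [pos[j] for j in range(len(ids)) if recombinants[ids[j]] and pos[j] < lo_c]
    right = [pos[j] for j in range(len(ids)) if recombinants[ids[j]] and pos[j] > hi_c]
    start = int(max(prior.start, max(left))) if left else prior.start
    end = int(min(prior.end, min(right))) if right else prior.end
    region = CandidateRegion(prior.chrom, start, end, prior.level, prior.source)
    return NarrowResult(region=region, recombinants=recombinants,
                        cosegregating=cosegregating)


def average_marker_spacing_cm(total_cm: float, n_bin_markers: int) -> float:
    """Mean spacing of a genetic map, following the map-total / marker-count
    reporting convention (divides by the marker count, not the gap count)."""
    if n_bin_markers < 1:
        raise ValueError("need at least one marker")
    return total_cm / n_bin_markers
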