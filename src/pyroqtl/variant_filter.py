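"""Quality and parental-difference filters for pooled variant records.

The pipeline works on biallelic sites where the maternal wild-type line (RZ,
the reference) and the paternal red mutant (HT, the alternate) carry fixed,
different alleles.  Records carry per-pool allele depths; the filters below
enforce the read-depth / mapping-quality / adjacent-site rules applied before
any SNP-index arithmetic, and then restrict to sites that are genuine fixed
differences between the parents.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "VariantRecord",
    "FilterThresholds",
    "filter_variants",
    "extract_parental_differences",
]


@dataclass
class VariantRecord:
    """One biallelic site with per-pool allele depths.

    ``pools`` maps a pool name (e.g. ``"P1"``, ``"RT24"``) to a pair
    ``(alt_reads, total_reads)`` where *alt* is the HT (paternal) allele.
    ``mq`` is the RMS mapping quality; ``None`` means unknown and is treated
    as passing the mapping-quality rule (it cannot be assessed).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    mq: float | None = None
    pools: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for name, (alt, total) in self.pools.items():
            if not (0 <= alt <= total):
                raise ValueError(
                    f"{self.chrom}:{self.pos} pool {name}: need 0 <= alt <= total, "
                    f"got ({alt}, {total})"
                )


@dataclass(frozen=True)
class FilterThresholds:
    """Site-level thresholds (all bounds inclusive).

    Depth bounds are enforced on every pool entering the downstream
    delta-index computation (both progeny bulks), since a low-coverage pool
    makes the per-pool index unreliable regardless of the other pool.
    """

    min_depth: int = 4
    max_depth: int = 1000
    min_mq: float = 20.0
    min_gap: int = 5  # adjacent sites closer than this (bp) are both removed
    min_parent_alt_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")
        if min(self.min_depth, self.min_gap) < 0 or self.min_mq < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0 < self.min_parent_alt_fraction <= 1:
            raise ValueError("min_parent_alt_fraction must be in (0, 1]")


def _check_sorted_unique(records: Sequence[VariantRecord]) -> None:
    seen_chroms: dict[str, int] = {}
    prev_chrom = None
    prev_pos = -1
    for rec in records:
        if rec.chrom != prev_chrom:
            if rec.chrom in seen_chroms:
                raise ValueError(f"records not sorted: chromosome {rec.chrom} interleaved")
            seen_chroms[rec.chrom] = 1
            prev_chrom, prev_pos = rec.chrom, rec.pos
            continue
        if rec.pos == prev_pos:
            raise ValueError(f"duplicate position {rec.chrom}:{rec.pos}")
        if rec.pos < prev_pos:
            raise ValueError(f"records not sorted at {rec.chrom}:{rec.pos}")
        prev_pos = rec.pos


def _adjacency_flags(records: Sequence[VariantRecord], min_gap: int) -> list[bool]:
    """True where a site has a neighbour closer than ``min_gap`` bp.

    Both members of a too-close pair are flagged (symmetric removal; avoids
    order dependence the asymmetric reading would introduce).
    """
    flagged = [False] * len(records)
    for i in range(1, len(records)):
        a, b = records[i - 1], records[i]
        if a.chrom == b.chrom and b.pos - a.pos < min_gap:
            flagged[i - 1] = True
            flagged[i] = True
    return flagged


def filter_variants(
    records: Sequence[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
    depth_pools: Iterable[str] | None = None,
) -> tuple[list[VariantRecord], Counter]:
    """Apply depth, mapping-quality and adjacent-site filters.

    Parameters
    ----------
    records
        Sorted by (chromosome, position), one record per site.
    depth_pools
        Pool names whose depth must satisfy the bounds.  Default: every pool
        present on each record.

    Returns
    -------
    (kept, removed_by_rule)
        ``removed_by_rule`` partitions the removed records by the *first*
        failing rule, in the order depth -> mapping_quality -> adjacency.
    """
    _check_sorted_unique(records)
    flagged_adjacent = _adjacency_flags(records, thresholds.min_gap)

    kept: list[VariantRecord] = []
    removed: Counter = Counter()
    for rec, adjacent in zip(records, flagged_adjacent):
        pools = list(depth_pools) if depth_pools is not None else list(rec.pools)
        depths = [rec.pools[p][1] for p in pools]
        if any(d < thresholds.min_depth or d > thresholds.max_depth for d in depths):
            removed["depth"] += 1
        elif rec.mq is not None and rec.mq < thresholds.min_mq:
            removed["mapping_quality"] += 1
        elif adjacent:
            removed["adjacency"] += 1
        else:
            kept.append(rec)
    return kept, removed


def extract_parental_differences(
    records: Sequence[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
    parent_pool: str = "P1",
    bulk_pools: Sequence[str] = ("RT", "WT"),
) -> tuple[list[VariantRecord], Counter]:
    """Restrict to sites fixed for the alternate allele in the HT parent.

    A haploid parent should be effectively fixed; the fraction threshold
    (default 0.9 rather than 1.0) tolerates sampling/alignment noise.  Sites
    with zero coverage in either progeny bulk are dropped too — no index can
    be computed there.
    """
    kept: list[VariantRecord] = []
    removed: Counter = Counter()
    for rec in records:
        if parent_pool not in rec.pools:
            raise KeyError(
                f"{rec.chrom}:{rec.pos}: parent pool {parent_pool!r} missing"
            )
        alt, total = rec.pools[parent_pool]
        if total == 0 or alt / total < thresholds.min_parent_alt_fraction:
            removed["not_parental_difference"] += 1
            continue
        if any(rec.pools[p][1] == 0 for p in bulk_pools):
            removed["uncovered_bulk"] += 1
            continue
        kept.append(rec)
    return kept, removed
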