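"""Variant-effect classification, DEG filtering and candidate-gene ranking.

A candidate region from the mapping stages typically contains dozens to
hundreds of gene models.  The prioritization implemented here mirrors the
usual map-then-expression triage: classify each region SNP against the gene
models (coding non-synonymous > regulatory flank > synonymous > intergenic),
select differentially expressed genes (|log2 fold change| > 1 between the
mutant and wild-type parents), and rank the region genes by the combination
of variant severity and expression change.  A 2^-ddCt helper supports qPCR
validation arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .qtlseq import CandidateRegion

__all__ = [
    "GeneModel",
    "SnpEffect",
    "classify_snp_effect",
    "protein_length",
    "deg_filter",
    "prioritize",
    "ddct",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: effect classes, most severe first
EFFECT_CLASSES = (
    "coding_nonsynonymous",
    "coding_synonymous",
    "upstream",
    "downstream",
    "intergenic",
)


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene model with CDS coordinates and sequence.

    ``cds_segments`` are 1-based inclusive genomic intervals, sorted and
    non-overlapping.  ``cds_seq`` is the spliced coding sequence in reading
    direction (already reverse-complemented for minus-strand genes); its
    length must be a multiple of 3 and equal the summed segment lengths.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    cds_seq: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        segs = self.cds_segments
        if not segs:
            raise ValueError(f"{self.gene_id}: no CDS segments")
        for (s, e) in segs:
            if s > e or s < 1:
                raise ValueError(f"{self.gene_id}: bad CDS segment ({s}, {e})")
        for (_, e1), (s2, _) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: CDS segments overlap or unsorted")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not a multiple of 3")
        if self.cds_seq is not None and len(self.cds_seq) != self.cds_length:
            raise ValueError(f"{self.gene_id}: CDS sequence length mismatch")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_segments[0][0], self.cds_segments[-1][1]

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the spliced CDS
        (reading direction), or None when the position is not coding."""
        if self.strand == "+":
            off = 0
            for s, e in self.cds_segments:
                if s <= pos <= e:
                    return off + (pos - s)
                off += e - s + 1
        else:
            off = 0
            for s, e in reversed(self.cds_segments):
                if s <= pos <= e:
                    return off + (e - pos)
                off += e - s + 1
        return None


@dataclass(frozen=True)
class SnpEffect:
    """Classified consequence of one SNP.

    Coding classes carry the gene id, 1-based codon (residue) index and the
    reference/alternate amino acids; regulatory classes carry the gene id
    only; intergenic carries neither.
    """

    chrom: str
    pos: int
    effect_class: str
    gene_id: str | None = None
    codon_index: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None


def _oriented(base: str, strand: str) -> str:
    if len(base) != 1 or base.upper() not in "ACGT":
        raise ValueError(f"ambiguous or non-SNP allele {base!r}")
    return base.upper().translate(_COMPLEMENT) if strand == "-" else base.upper()


def _coding_effect(gene: GeneModel, pos: int, ref: str, alt: str) -> SnpEffect:
    if gene.cds_seq is None:
        raise ValueError(f"{gene.gene_id}: SNP in CDS but CDS sequence missing")
    off = gene.cds_offset(pos)
    assert off is not None
    codon_index = off // 3 + 1
    within = off % 3
    codon = gene.cds_seq[3 * (codon_index - 1): 3 * codon_index].upper()
    ref_o, alt_o = _oriented(ref, gene.strand), _oriented(alt, gene.strand)
    if codon[within] != ref_o:
        raise ValueError(
            f"{gene.gene_id}: CDS base {codon[within]} at offset {off} does not "
            f"match reference allele {ref_o}"
        )
    alt_codon = codon[:within] + alt_o + codon[within + 1:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    klass = "coding_synonymous" if ref_aa == alt_aa else "coding_nonsynonymous"
    return SnpEffect(gene.chrom, pos, klass, gene.gene_id, codon_index, ref_aa, alt_aa)


def classify_snp_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    genes: Sequence[GeneModel],
    flank: int = 1000,
) -> SnpEffect:
    """Classify one SNP against a set of gene models.

    Coding consequences (strand-aware codon translation with the standard
    genetic code) beat regulatory-flank assignment; a SNP within ``flank`` bp
    of more than one gene is assigned to the nearest.  Everything else is
    intergenic.
    """
    if pos < 1:
        raise ValueError("position must be >= 1")
    same_chrom = [g for g in genes if g.chrom == chrom]
    for gene in same_chrom:
        if gene.cds_offset(pos) is not None:
            return _coding_effect(gene, pos, ref, alt)

    best: tuple[int, GeneModel] | None = None
    for gene in same_chrom:
        lo, hi = gene.span
        if lo - flank <= pos <= hi + flank:
            dist = max(lo - pos, pos - hi, 0)
            if best is None or dist < best[0]:
                best = (dist, gene)
    if best is not None:
        _, gene = best
        lo, hi = gene.span
        before = pos < lo
        # orientation: the 5' side of a minus-strand gene is its right side
        upstream = before if gene.strand == "+" else not before
        klass = "upstream" if upstream else "downstream"
        return SnpEffect(chrom, pos, klass, gene.gene_id)
    return SnpEffect(chrom, pos, "intergenic")


def protein_length(cds_length: int | None = None, seq: str | None = None) -> int:
    """Residue count of a CDS given its length and/or sequence.

    With only a length: length/3 (the common CDS-excludes-stop reporting
    convention).  With a sequence: one terminal stop codon, if present, is
    trimmed before counting.
    """
    if seq is not None:
        if len(seq) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")
        aa = str(Seq(seq).translate())
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            raise ValueError("internal stop codon in CDS")
        return len(aa)
    if cds_length is None:
        raise ValueError("need cds_length or seq")
    if cds_length % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    return cds_length // 3


def deg_filter(expression: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Differentially expressed genes: detected and |log2FC| strictly > threshold.

    Expects columns ``gene_id``, ``log2fc`` and optionally ``detected``
    (missing column means all detected).  Adds a ``direction`` column
    (up/down).  Genes with no detected expression never qualify.
    """
    df = expression.copy()
    if "detected" not in df.columns:
        df["detected"] = True
    keep = df["detected"].astype(bool) & (df["log2fc"].abs() > threshold)
    out = df.loc[keep, ["gene_id", "log2fc"]].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out.reset_index(drop=True)


def prioritize(
    region: CandidateRegion,
    genes: Sequence[GeneModel],
    effects: Iterable[SnpEffect],
    expression: pd.DataFrame,
    deg_threshold: float = 1.0,
) -> pd.DataFrame:
    """Rank genes overlapping the candidate region.

    Rank 1: DEG carrying a coding non-synonymous SNP; rank 2: DEG with a
    regulatory (up/downstream) SNP; rank 3: DEG without a SNP consequence;
    rank 4: everything else in the region (SNP-bearing non-DEGs and genes
    with neither).  Ties break by |log2FC| descending, then position.
    """
    degs = deg_filter(expression, deg_threshold)
    deg_lfc = dict(zip(degs["gene_id"], degs["log2fc"]))
    lfc_all = dict(zip(expression["gene_id"], expression["log2fc"]))

    best_effect: dict[str, str] = {}
    severity = {k: i for i, k in enumerate(EFFECT_CLASSES)}
    for eff in effects:
        if eff.gene_id is None:
            continue
        cur = best_effect.get(eff.gene_id)
        if cur is None or severity[eff.effect_class] < severity[cur]:
            best_effect[eff.gene_id] = eff.effect_class

    rows = []
    for gene in genes:
        lo, hi = gene.span
        if gene.chrom != region.chrom or hi < region.start or lo > region.end:
            continue
        is_deg = gene.gene_id in deg_lfc
        eff = best_effect.get(gene.gene_id)
        if is_deg and eff == "coding_nonsynonymous":
            rank = 1
        elif is_deg and eff in ("upstream", "downstream"):
            rank = 2
        elif is_deg:
            rank = 3
        else:
            rank = 4
        lfc = lfc_all.get(gene.gene_id, np.nan)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "chrom": gene.chrom,
                "start": lo,
                "end": hi,
                "rank": rank,
                "effect": eff or "none",
                "log2fc": lfc,
                "is_deg": is_deg,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "rank", "effect", "log2fc", "is_deg"],
    )
    if df.empty:
        return df
    df["_abs"] = df["log2fc"].abs().fillna(0.0)
    df = df.sort_values(["rank", "_abs", "start"], ascending=[True, False, True])
    return df.drop(columns="_abs").reset_index(drop=True)


def ddct(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,control - Ct_ref,control).
    """
    vals = (ct_target_test, ct_ref_test, ct_target_control, ct_ref_control)
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("Ct values must be finite")
    d = (ct_target_test - ct_ref_test) - (ct_target_control - ct_ref_control)
    return float(2.0 ** -d)
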