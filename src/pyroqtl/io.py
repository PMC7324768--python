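"""Readers and writers for the on-disk formats the pipeline exchanges.

Intervals are 1-based inclusive in VCF/GFF3/TSV and 0-based half-open in
BED; conversion happens only here, at the boundary.  VCF parsing goes
through cyvcf2 (htslib); GFF3 parsing through gffutils; FASTA through
Biopython.  Writers emit plain text with no timestamps so identical inputs
give byte-identical outputs.
"""

from __future__ import annotations

import os
import tempfile
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .candidate_genes import GeneModel
from .qtlseq import CandidateRegion
from .variant_filter import VariantRecord

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_gff3",
    "read_gene_models",
    "write_cds_fasta",
    "write_regions_tsv",
    "read_regions_tsv",
    "write_regions_bed",
    "region_to_bed",
    "bed_to_region",
]


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | os.PathLike,
    pool_names: Sequence[str] | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write pooled variant records as VCF 4.2 with AD/DP per pool column."""
    if pool_names is None:
        pool_names = list(records[0].pools) if records else []
    lines = ["##fileformat=VCFv4.2"]
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            lines.append(f"##contig=<ID={chrom},length={length}>")
    else:
        for chrom in dict.fromkeys(r.chrom for r in records):
            lines.append(f"##contig=<ID={chrom}>")
    lines += [
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(pool_names),
    ]
    for rec in records:
        info = f"MQ={rec.mq:g}" if rec.mq is not None else "."
        fields = [rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, ".", "PASS",
                  info, "AD:DP"]
        for name in pool_names:
            alt, total = rec.pools[name]
            fields.append(f"{total - alt},{alt}:{total}")
        lines.append("\t".join(fields))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str | os.PathLike) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF with per-pool AD/DP into variant records.

    Multiallelic records and records lacking AD raise with the offending
    position named.  CRLF line endings are normalised before parsing.
    """
    from cyvcf2 import VCF

    path = os.fspath(path)
    with open(path, "rb") as fh:
        head = fh.read(4096)
    tmp = None
    if b"\r\n" in head:
        with open(path, "rb") as fh:
            data = fh.read().replace(b"\r\n", b"\n")
        tmp = tempfile.NamedTemporaryFile(suffix=".vcf", delete=False)
        tmp.write(data)
        tmp.close()
        path = tmp.name
    try:
        vcf = VCF(path)
        pool_names = list(vcf.samples)
        records: list[VariantRecord] = []
        for v in vcf:
            if len(v.ALT) != 1:
                raise ValueError(
                    f"multiallelic record at {v.CHROM}:{v.POS}; "
                    "the pipeline handles biallelic parent differences only"
                )
            try:
                ad = v.format("AD")
            except KeyError:
                ad = None
            if ad is None:
                raise ValueError(f"record at {v.CHROM}:{v.POS} lacks the AD field")
            mq = v.INFO.get("MQ")
            pools = {}
            for i, name in enumerate(pool_names):
                ref_reads, alt_reads = int(ad[i][0]), int(ad[i][1])
                pools[name] = (alt_reads, ref_reads + alt_reads)
            records.append(
                VariantRecord(chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=v.ALT[0],
                              mq=float(mq) if mq is not None else None, pools=pools)
            )
        return records, pool_names
    finally:
        if tmp is not None:
            os.unlink(tmp.name)


def write_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene/mRNA/CDS features, 1-based inclusive."""
    lines = ["##gff-version 3"]
    for g in genes:
        lo, hi = g.span
        attrs = f"ID={g.gene_id};Name={g.gene_id}"
        lines.append("\t".join(
            [g.chrom, "pyroqtl", "gene", str(lo), str(hi), ".", g.strand, ".", attrs]))
        mrna = f"{g.gene_id}.t1"
        lines.append("\t".join(
            [g.chrom, "pyroqtl", "mRNA", str(lo), str(hi), ".", g.strand, ".",
             f"ID={mrna};Parent={g.gene_id}"]))
        # CDS phase: bases to skip to reach the next codon start
        done = 0
        segs = g.cds_segments if g.strand == "+" else tuple(reversed(g.cds_segments))
        phased = []
        for s, e in segs:
            phase = (3 - done % 3) % 3
            phased.append((s, e, phase))
            done += e - s + 1
        for s, e, phase in sorted(phased):
            lines.append("\t".join(
                [g.chrom, "pyroqtl", "CDS", str(s), str(e), ".", g.strand,
                 str(phase), f"ID={g.gene_id}.cds;Parent={mrna}"]))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def write_cds_fasta(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        for g in genes:
            if g.cds_seq is None:
                continue
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.cds_seq), 60):
                fh.write(g.cds_seq[i:i + 60] + "\n")


def read_gene_models(
    gff_path: str | os.PathLike, cds_fasta: str | os.PathLike | None = None
) -> list[GeneModel]:
    """Assemble gene models from a GFF3 file plus an optional CDS FASTA
    (records keyed by gene id supply the coding sequences)."""
    import gffutils

    db = gffutils.create_db(
        os.fspath(gff_path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    seqs: dict[str, str] = {}
    if cds_fasta is not None:
        seqs = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(os.fspath(cds_fasta), "fasta")}
    genes = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = gene.id
        segs = sorted(
            (c.start, c.end)
            for c in db.children(gene, featuretype="CDS")
        )
        genes.append(
            GeneModel(gene_id=gid, chrom=gene.seqid, strand=gene.strand,
                      cds_segments=tuple(segs), cds_seq=seqs.get(gid))
        )
    return genes


def write_regions_tsv(regions: Sequence[CandidateRegion], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start, "end": r.end,
          "length_bp": r.end - r.start + 1, "level": r.level, "source": r.source}
         for r in regions]
    )
    df.to_csv(path, sep="\t", index=False)


def read_regions_tsv(path: str | os.PathLike) -> list[CandidateRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"source": str}, keep_default_na=False)
    return [
        CandidateRegion(str(r.chrom), int(r.start), int(r.end),
                        int(r.level), str(r.source))
        for r in df.itertuples()
    ]


def region_to_bed(region: CandidateRegion) -> tuple[str, int, int]:
    """1-based inclusive -> BED 0-based half-open."""
    return region.chrom, region.start - 1, region.end


def bed_to_region(chrom: str, start: int, end: int,
                  level: int = 95, source: str = "") -> CandidateRegion:
    """BED 0-based half-open -> 1-based inclusive."""
    return CandidateRegion(chrom, start + 1, end, level, source)


def write_regions_bed(regions: Sequence[CandidateRegion], path: str | os.PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        for r in regions:
            chrom, start, end = region_to_bed(r)
            fh.write(f"{chrom}\t{start}\t{end}\t{r.source or '.'}\t{r.level}\n")
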