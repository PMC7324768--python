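"""Simulator for a haploid x haploid *Pyropia* cross with ordered tetrads.

The wild maternal line (RZ, reference) is crossed to the red paternal mutant
(HT).  Meiosis during conchospore germination yields four joined haploid
products — an ordered tetrad — that develop into the 1-4 single-genotype
sectors of one chimeric blade.  The simulator plants a single causal locus
(phenotype RT iff the sector carries the HT allele there), recombines with a
Haldane (no-interference) crossover model, pools sectors of each phenotype
into sequencing bulks with binomial read sampling at Poisson depth, and emits
gene models / coding sequences / an expression table with one planted
non-synonymous candidate gene plus decoy DEGs, together with truth tables.

Default study conditions: three chromosomes (~108 Mb), ~20,000
parent-differentiating markers, bulk pairs of 24 and 56 sectors, 100x mean
depth, and a genetic map totalling ~472 cM (4.37 cM/Mb).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_filter import VariantRecord
from . import candidate_genes as cg

__all__ = [
    "GenomeSpec",
    "Tetrad",
    "SectorSample",
    "BulkCounts",
    "AnnotationSet",
    "SyntheticDataset",
    "simulate_parents",
    "simulate_tetrad",
    "simulate_tetrads",
    "assemble_population",
    "sample_bulk",
    "build_bulks",
    "bulk_to_records",
    "simulate_annotation_and_expression",
    "simulate_dataset",
]

#: default blade sector-count distribution over 1-4 sectors: sectored blades
#: are more frequent than unsectored ones
SECTOR_DIST_DEFAULT = (0.1, 0.3, 0.3, 0.3)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = np.array(
    [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
     if a + b + c not in _STOPS]
)


def _default_chroms() -> dict[str, int]:
    return {"chr1": 45_000_000, "chr2": 35_000_000, "chr3": 28_000_000}


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of the simulated cross.

    ``recomb_cm_per_mb`` of 4.37 makes the three-chromosome ~108 Mb genome
    span ~472 cM.  The causal locus defaults to the distal end of
    chromosome 1.
    """

    chrom_lengths: Mapping[str, int] = field(default_factory=_default_chroms)
    n_markers: int = 20_000
    causal_chrom: str = "chr1"
    causal_pos: int = 41_578_129
    recomb_cm_per_mb: float = 4.37
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("need at least one chromosome")
        if any(l < 1 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be >= 1")
        if self.n_markers < 1:
            raise ValueError("need at least one marker")
        if self.causal_chrom not in self.chrom_lengths:
            raise ValueError(f"causal chromosome {self.causal_chrom!r} unknown")
        if not 1 <= self.causal_pos <= self.chrom_lengths[self.causal_chrom]:
            raise ValueError("causal position off its chromosome")
        if self.recomb_cm_per_mb < 0:
            raise ValueError("recombination rate must be >= 0")


def _draw_positions(rng: np.random.Generator, length: int, count: int,
                    exclude: Sequence[tuple[int, int]] = ()) -> np.ndarray:
    """Distinct random positions in [1, length], avoiding excluded intervals."""
    have: np.ndarray = np.empty(0, dtype=np.int64)
    guard = 0
    while have.size < count and guard < 50:
        draw = rng.integers(1, length + 1, size=count - have.size + 16)
        for (s, e) in exclude:
            draw = draw[(draw < s) | (draw > e)]
        have = np.unique(np.concatenate([have, draw]))
        guard += 1
    return np.sort(have[:count])


def simulate_parents(
    spec: GenomeSpec,
    rng: np.random.Generator | None = None,
    exclude: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """Fixed biallelic differences between the parents.

    RZ carries the reference allele and HT the alternate at every marker
    (haploid parents, fixed differences).  Markers are placed uniformly,
    proportionally to chromosome length; the causal locus itself is always a
    marker (ref A, alt C — the planted coding change).  ``exclude`` removes
    intervals from random placement (used to keep the annotated gene zone
    free of incidental coding hits).
    """
    spec.__post_init__()  # validate (frozen dataclass; cheap re-check)
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    total = sum(spec.chrom_lengths.values())
    rows = []
    for chrom, length in spec.chrom_lengths.items():
        k = max(1, round(spec.n_markers * length / total))
        zones = list((exclude or {}).get(chrom, ()))
        if chrom == spec.causal_chrom:
            zones.append((spec.causal_pos, spec.causal_pos))
        pos = _draw_positions(rng, length, k, zones)
        ref_i = rng.integers(0, 4, size=pos.size)
        alt_i = (ref_i + rng.integers(1, 4, size=pos.size)) % 4
        for p, r, a in zip(pos, _BASES[ref_i], _BASES[alt_i]):
            rows.append((chrom, int(p), r, a))
        if chrom == spec.causal_chrom:
            rows.append((chrom, spec.causal_pos, "A", "C"))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    df = df.sort_values(["chrom", "pos"], key=_chrom_sort_key(spec)).reset_index(drop=True)
    return df


def _chrom_sort_key(spec: GenomeSpec):
    order = {c: i for i, c in enumerate(spec.chrom_lengths)}

    def key(col: pd.Series) -> pd.Series:
        if col.name == "chrom":
            return col.map(order)
        return col

    return key


@dataclass
class Tetrad:
    """Four ordered haploid meiotic products.

    ``products`` is a (4, n_markers) array of alleles (0 = RZ, 1 = HT);
    products 0-1 and 2-3 are sister pairs (same centromere).  At every
    marker exactly two products carry each parental allele.
    """

    products: np.ndarray
    breakpoints: dict[str, list[int]] = field(default_factory=dict)


def _marker_layout(markers: pd.DataFrame) -> list[tuple[str, np.ndarray, np.ndarray]]:
    layout = []
    for chrom in dict.fromkeys(markers["chrom"]):
        idx = np.flatnonzero((markers["chrom"] == chrom).to_numpy())
        layout.append((chrom, idx, markers["pos"].to_numpy()[idx]))
    return layout


def simulate_tetrad(
    markers: pd.DataFrame,
    spec: GenomeSpec,
    rng: np.random.Generator,
    _layout: list | None = None,
) -> Tetrad:
    """One meiosis under the Haldane model.

    Per chromosome the chiasma count is Poisson with mean twice the map
    length in Morgans (each chiasma involves one chromatid from each
    homologue, so every product expects the map length in crossovers, giving
    Haldane's map function with no interference).  Breakpoints are uniform;
    chromatid choice is uniform among non-sister pairs.  Chromosomes assort
    independently onto the four ordered positions, preserving sister pairs.
    """
    if len(markers) == 0:
        raise ValueError("need at least one marker")
    if spec.recomb_cm_per_mb < 0:
        raise ValueError("negative recombination rate")
    layout = _layout if _layout is not None else _marker_layout(markers)
    n = len(markers)
    products = np.empty((4, n), dtype=np.int8)
    breakpoints: dict[str, list[int]] = {}
    for chrom, idx, pos in layout:
        length = spec.chrom_lengths[chrom]
        morgans = length / 1e6 * spec.recomb_cm_per_mb / 100.0
        n_x = rng.poisson(2.0 * morgans)
        bps = np.sort(rng.integers(1, length + 1, size=n_x))
        # Chiasmata connect one chromatid axis of each homologue (axes 0-1
        # carry RZ, 2-3 carry HT); the four product molecules move between
        # axes at each junction.  Tracking axis occupancy segment by segment
        # reproduces the classical exchange diagram: exact 2:2 segregation
        # and Haldane's map function with no interference.
        chromatids = np.empty((4, idx.size), dtype=np.int8)
        axis_allele = np.array([0, 0, 1, 1], dtype=np.int8)
        occ = np.array([0, 1, 2, 3])  # axis -> product currently on it
        prev_cut = 0
        for bp in bps:
            cut = int(np.searchsorted(pos, bp, side="right"))
            chromatids[occ, prev_cut:cut] = axis_allele[:, None]
            a = rng.integers(0, 2)
            b = 2 + rng.integers(0, 2)
            occ[a], occ[b] = occ[b], occ[a]
            prev_cut = cut
        chromatids[occ, prev_cut:] = axis_allele[:, None]
        breakpoints[chrom] = [int(b) for b in bps]
        # independent assortment: which sister pair occupies positions 0-1
        order = [0, 1, 2, 3] if rng.integers(0, 2) == 0 else [2, 3, 0, 1]
        if rng.integers(0, 2):
            order[0], order[1] = order[1], order[0]
        if rng.integers(0, 2):
            order[2], order[3] = order[3], order[2]
        products[:, idx] = chromatids[order]
    return Tetrad(products=products, breakpoints=breakpoints)


def simulate_tetrads(
    markers: pd.DataFrame, spec: GenomeSpec, count: int, rng: np.random.Generator
) -> list[Tetrad]:
    layout = _marker_layout(markers)
    return [simulate_tetrad(markers, spec, rng, _layout=layout) for _ in range(count)]


@dataclass
class SectorSample:
    """One single-genotype blade sector with its phenotype."""

    sample_id: str
    genotype: np.ndarray        # alleles over markers, 0=RZ / 1=HT
    phenotype: str              # "WT" or "RT"
    blade_id: str
    sector_count: int           # sectors of the blade this sector belongs to


def assemble_population(
    tetrads: Sequence[Tetrad],
    markers: pd.DataFrame,
    spec: GenomeSpec,
    sector_dist: Sequence[float] = SECTOR_DIST_DEFAULT,
    rng: np.random.Generator | None = None,
) -> list[SectorSample]:
    """Develop each tetrad into a chimeric blade of 1-4 sectors.

    The blade's sector count is drawn from ``sector_dist``; its sectors are a
    uniform subset of the tetrad's four products, so the expected WT:RT
    sector ratio is 1:1.  The phenotype is red (RT) iff the sector carries
    the HT allele at the causal locus.
    """
    if not tetrads:
        raise ValueError("empty tetrad list")
    dist = np.asarray(sector_dist, dtype=float)
    if dist.shape != (4,) or abs(dist.sum() - 1) > 1e-9 or (dist < 0).any():
        raise ValueError("sector-count distribution must be 4 probabilities summing to 1")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    causal_idx = _causal_index(markers, spec)
    samples: list[SectorSample] = []
    for t, tetrad in enumerate(tetrads):
        k = int(rng.choice(4, p=dist)) + 1
        chosen = np.sort(rng.choice(4, size=k, replace=False))
        blade_id = f"B{t:05d}"
        for j, prod in enumerate(chosen):
            geno = tetrad.products[prod]
            phenotype = "RT" if geno[causal_idx] == 1 else "WT"
            samples.append(
                SectorSample(
                    sample_id=f"{blade_id}S{j + 1}",
                    genotype=geno,
                    phenotype=phenotype,
                    blade_id=blade_id,
                    sector_count=k,
                )
            )
    return samples


def _causal_index(markers: pd.DataFrame, spec: GenomeSpec) -> int:
    hit = np.flatnonzero(
        ((markers["chrom"] == spec.causal_chrom) & (markers["pos"] == spec.causal_pos)).to_numpy()
    )
    if hit.size != 1:
        raise ValueError("causal locus must appear exactly once in the marker table")
    return int(hit[0])


@dataclass
class BulkCounts:
    """Per-marker sequencing counts for each pool.

    ``pools`` maps pool name to (alt_reads, total_reads) arrays over markers;
    ``members`` records which sample ids went into each bulk (the parent pool
    has no members).
    """

    markers: pd.DataFrame
    pools: dict[str, tuple[np.ndarray, np.ndarray]]
    members: dict[str, list[str]]
    mean_depth: float


def sample_bulk(
    samples: Sequence[SectorSample],
    phenotype: str,
    n: int,
    mean_depth: float,
    rng: np.random.Generator,
    pool: Sequence[SectorSample] | None = None,
) -> tuple[list[SectorSample], np.ndarray, np.ndarray]:
    """Pool ``n`` sectors of one phenotype and sample reads at each marker.

    Depth per marker is Poisson(``mean_depth``); HT-supporting reads are
    Binomial(depth, bulk HT-allele frequency).  Returns the chosen samples
    and the (alt_reads, depth) arrays.
    """
    if mean_depth <= 0:
        raise ValueError("mean depth must be > 0")
    candidates = [s for s in (pool if pool is not None else samples)
                  if s.phenotype == phenotype]
    if len(candidates) < n:
        raise ValueError(
            f"need {n} samples with phenotype {phenotype}, have {len(candidates)}"
        )
    chosen_idx = rng.choice(len(candidates), size=n, replace=False)
    chosen = [candidates[i] for i in sorted(chosen_idx)]
    geno = np.stack([s.genotype for s in chosen])
    freq = geno.mean(axis=0)
    depth = rng.poisson(mean_depth, size=freq.size)
    alt = rng.binomial(depth, freq)
    return chosen, alt, depth


def build_bulks(
    samples: Sequence[SectorSample],
    markers: pd.DataFrame,
    bulk_sizes: Mapping[str, int] = {"RT24": 24, "WT24": 24, "RT56": 56, "WT56": 56},
    mean_depth: float = 100.0,
    rng: np.random.Generator | None = None,
    seed: int = 1,
    parent_pool: str = "P1",
) -> BulkCounts:
    """Construct the parent pool plus phenotype bulks of the requested sizes.

    Pool names must start with the phenotype they collect ("RT..."/"WT...").
    The HT parent pool is fixed for the alternate allele (reads = depth).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    pools: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    members: dict[str, list[str]] = {}
    n_markers = len(markers)
    depth = rng.poisson(mean_depth, size=n_markers)
    pools[parent_pool] = (depth.copy(), depth)
    members[parent_pool] = []
    for name, n in bulk_sizes.items():
        phenotype = name[:2]
        if phenotype not in ("RT", "WT"):
            raise ValueError(f"pool name {name!r} must start with RT or WT")
        chosen, alt, d = sample_bulk(samples, phenotype, n, mean_depth, rng)
        pools[name] = (alt, d)
        members[name] = [s.sample_id for s in chosen]
    return BulkCounts(markers=markers, pools=pools, members=members, mean_depth=mean_depth)


def bulk_to_records(bulk: BulkCounts, mq: float = 60.0) -> list[VariantRecord]:
    """Flatten bulk counts into per-site variant records (all pools)."""
    records = []
    m = bulk.markers
    chroms = m["chrom"].tolist()
    pos = m["pos"].tolist()
    refs = m["ref"].tolist()
    alts = m["alt"].tolist()
    names = list(bulk.pools)
    arrays = [bulk.pools[n] for n in names]
    for i in range(len(m)):
        pools = {n: (int(a[i]), int(d[i])) for n, (a, d) in zip(names, arrays)}
        records.append(
            VariantRecord(chrom=chroms[i], pos=pos[i], ref=refs[i], alt=alts[i],
                          mq=mq, pools=pools)
        )
    return records


@dataclass
class AnnotationSet:
    """Gene models, planted SNPs and expression table for the causal region."""

    genes: list[cg.GeneModel]
    planted_snps: pd.DataFrame      # chrom, pos, ref, alt, effect_class, gene_id
    expression: pd.DataFrame        # gene_id, log2fc, detected
    causal_gene_id: str
    region: tuple[str, int, int]    # annotated zone (chrom, start, end)
    deg_gene_ids: list[str]


def _random_cds(rng: np.random.Generator, n_codons: int, trailing_stop: bool = True) -> str:
    body = "".join(rng.choice(_NONSTOP_CODONS, size=n_codons - 2))
    return "ATG" + body + ("TAA" if trailing_stop else
                           str(rng.choice(_NONSTOP_CODONS)))


def simulate_annotation_and_expression(
    spec: GenomeSpec,
    rng: np.random.Generator | None = None,
    n_genes: int = 141,
    n_intergenic_snps: int = 24,
    n_regulatory_snps: int = 2,
    n_decoy_degs: int = 11,
    causal_log2fc: float = 2.7,
    flank: int = 1000,
) -> AnnotationSet:
    """Gene models around the causal locus with planted variant/DEG truth.

    One planted gene carries the causal locus inside its single-exon CDS such
    that the A->C change converts a CAA (Gln) codon at residue 331 to CCA
    (Pro); its CDS is 1,338 bp.  Decoy DEGs (|log2FC| > 1) and two regulatory
    SNPs in neighbouring flanks emulate the triage problem; intergenic SNPs
    stay clear of all gene flanks.  One gene is flagged as not expressed.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    chrom = spec.causal_chrom
    region_start = max(1, spec.causal_pos - 100_000)
    region_end = region_start + 1_421_871
    if region_end > spec.chrom_lengths[chrom]:
        raise ValueError("annotated region exceeds the causal chromosome")
    slot = (region_end - region_start + 1) // n_genes
    max_len_bp = 1500
    if slot < max_len_bp + 2 * flank + 200:
        raise ValueError("region too small for requested gene count")

    causal_id = None
    genes: list[cg.GeneModel] = []
    causal_slot = (spec.causal_pos - region_start) // slot
    for i in range(n_genes):
        gene_id = f"Py{i + 1:05d}"
        slot_start = region_start + i * slot
        if i == causal_slot:
            causal_id = gene_id
            n_codons = 446
            start = spec.causal_pos - 991      # codon 331, 2nd base
            seq = list(_random_cds(rng, n_codons, trailing_stop=False))
            seq[990:993] = "CAA"               # Gln codon hit by the A->C change
            seq = "".join(seq)
        else:
            n_codons = int(rng.integers(150, max_len_bp // 3))
            lo = slot_start + flank
            hi = slot_start + slot - flank - 3 * n_codons - 1
            start = int(rng.integers(lo, max(lo + 1, hi)))
            seq = _random_cds(rng, n_codons)
        end = start + 3 * n_codons - 1
        strand = "+" if (i == causal_slot or rng.integers(0, 2) == 0) else "-"
        genes.append(
            cg.GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                         cds_segments=((start, end),), cds_seq=seq)
        )

    snp_rows = [
        {"chrom": chrom, "pos": spec.causal_pos, "ref": "A", "alt": "C",
         "effect_class": "coding_nonsynonymous", "gene_id": causal_id}
    ]
    # regulatory SNPs in flanks of the causal gene's neighbours
    neighbours = [g for g in genes if g.gene_id != causal_id]
    for j in range(n_regulatory_snps):
        gene = neighbours[(causal_slot + j) % len(neighbours)]
        pos = gene.span[0] - 200 - j
        klass = "upstream" if gene.strand == "+" else "downstream"
        snp_rows.append({"chrom": chrom, "pos": int(pos), "ref": "G", "alt": "T",
                         "effect_class": klass, "gene_id": gene.gene_id})
    # intergenic SNPs: clear of every gene span +/- flank
    forbidden = [(g.span[0] - flank - 5, g.span[1] + flank + 5) for g in genes]
    taken = {r["pos"] for r in snp_rows}
    count = 0
    while count < n_intergenic_snps:
        pos = int(rng.integers(region_start, region_end + 1))
        if pos in taken or any(s <= pos <= e for s, e in forbidden):
            continue
        ref_i = int(rng.integers(0, 4))
        alt_i = (ref_i + int(rng.integers(1, 4))) % 4
        snp_rows.append({"chrom": chrom, "pos": pos, "ref": str(_BASES[ref_i]),
                         "alt": str(_BASES[alt_i]), "effect_class": "intergenic",
                         "gene_id": None})
        taken.add(pos)
        count += 1
    planted = pd.DataFrame(snp_rows).sort_values("pos").reset_index(drop=True)

    # expression: causal gene strongly up in HT; decoys; one silent gene
    gene_ids = [g.gene_id for g in genes]
    lfc = rng.uniform(-0.8, 0.8, size=n_genes)
    detected = np.ones(n_genes, dtype=bool)
    causal_i = gene_ids.index(causal_id)
    lfc[causal_i] = causal_log2fc
    others = [i for i in range(n_genes) if i != causal_i]
    decoys = rng.choice(others, size=n_decoy_degs + 1, replace=False)
    silent_i = int(decoys[-1])
    for i in decoys[:-1]:
        lfc[i] = rng.choice([-1, 1]) * rng.uniform(1.2, 3.0)
    detected[silent_i] = False
    lfc[silent_i] = 0.0
    expression = pd.DataFrame(
        {"gene_id": gene_ids, "log2fc": np.round(lfc, 4), "detected": detected}
    )
    deg_ids = sorted(
        expression.loc[expression["detected"] & (expression["log2fc"].abs() > 1.0),
                       "gene_id"]
    )
    return AnnotationSet(
        genes=genes,
        planted_snps=planted,
        expression=expression,
        causal_gene_id=causal_id,
        region=(chrom, region_start, region_end),
        deg_gene_ids=deg_ids,
    )


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces, plus the truth."""

    spec: GenomeSpec
    markers: pd.DataFrame
    samples: list[SectorSample]
    bulks: BulkCounts
    annotation: AnnotationSet
    truth: dict

    @property
    def causal_index(self) -> int:
        return _causal_index(self.markers, self.spec)


def simulate_dataset(
    spec: GenomeSpec = GenomeSpec(),
    n_tetrads: int = 220,
    bulk_sizes: Mapping[str, int] = {"RT24": 24, "WT24": 24, "RT56": 56, "WT56": 56},
    mean_depth: float = 100.0,
    sector_dist: Sequence[float] = SECTOR_DIST_DEFAULT,
) -> SyntheticDataset:
    """Run the whole generator: annotation, markers, meioses, blades, bulks.

    Random markers are kept out of the annotated gene zone; the planted
    region SNPs (1 coding + regulatory + intergenic) are added as markers
    instead, so the truth about coding consequences in the region is exact.
    """
    rng = np.random.default_rng(spec.seed)
    annotation = simulate_annotation_and_expression(spec, rng)
    chrom, zs, ze = annotation.region
    flank_pad = 2000
    markers = simulate_parents(
        spec, rng, exclude={chrom: [(zs - flank_pad, ze + flank_pad)]}
    )
    extra = annotation.planted_snps[annotation.planted_snps["pos"] != spec.causal_pos]
    add = extra[["chrom", "pos", "ref", "alt"]]
    markers = (
        pd.concat([markers, add], ignore_index=True)
        .sort_values(["chrom", "pos"], key=_chrom_sort_key(spec))
        .reset_index(drop=True)
    )
    tetrads = simulate_tetrads(markers, spec, n_tetrads, rng)
    samples = assemble_population(tetrads, markers, spec, sector_dist, rng)
    bulks = build_bulks(samples, markers, bulk_sizes, mean_depth, rng)
    truth = {
        "causal_chrom": spec.causal_chrom,
        "causal_pos": spec.causal_pos,
        "causal_gene_id": annotation.causal_gene_id,
        "deg_gene_ids": annotation.deg_gene_ids,
        "bulk_members": bulks.members,
        "planted_snps": annotation.planted_snps,
    }
    return SyntheticDataset(
        spec=spec, markers=markers, samples=samples, bulks=bulks,
        annotation=annotation, truth=truth,
    )
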