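"""End-to-end driver: simulate -> filter -> bulk scan -> confirm/narrow -> rank.

Mirrors the study design: two phenotype bulk pairs (24 and 56 sectors) are
scanned for delta(SNP-index) peaks, the pair-wise candidate regions are
intersected, a linkage-style LOD scan on an independent sample set confirms
the region, single-marker (KASP-style) genotyping of a larger sample set
narrows it via recombinants, and the region genes are ranked by variant
effect and differential expression.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from . import qtlseq as qc
from . import synthetic_cross as sc
from .candidate_genes import classify_snp_effect, prioritize
from .fine_mapping import (
    GenotypeMatrix,
    chi_square_segregation,
    lod_scan,
    narrow_by_recombinants,
    screen_and_bin_markers,
)
from .variant_filter import FilterThresholds, extract_parental_differences, filter_variants

__all__ = ["PipelineConfig", "PipelineResult", "run_in_memory", "run_pipeline",
           "config_from_yaml"]


@dataclass
class PipelineConfig:
    """All knobs of one synthetic-study run.

    ``seed`` drives the data generation; ``ci_seed`` drives the null-CI
    simulation (kept separate so identical CI configurations are reusable
    across replicate runs).
    """

    seed: int = 1
    n_markers: int = 20_000
    n_tetrads: int = 220
    mean_depth: float = 100.0
    bulk_pairs: dict = field(default_factory=lambda: {"24": ("RT24", "WT24", 24),
                                                      "56": ("RT56", "WT56", 56)})
    sector_dist: tuple = sc.SECTOR_DIST_DEFAULT
    causal_chrom: str = "chr1"
    causal_pos: int = 41_578_129
    recomb_cm_per_mb: float = 4.37
    # variant filters
    min_depth: int = 4
    max_depth: int = 1000
    min_mq: float = 20.0
    min_gap: int = 5
    min_parent_alt_fraction: float = 0.9
    # window scan
    window: int = 1_000_000
    step: int = 100_000
    min_snps_per_window: int = 3
    ci_replicates: int = 10_000
    ci_seed: int = 1
    level: int = 95
    # confirmation / narrowing
    linkage_samples: int = 84
    lod_permutations: int = 1000
    kasp_markers: int = 4
    kasp_samples: int = 320
    # candidate ranking
    flank: int = 1000
    deg_threshold: float = 1.0

    def validate(self) -> None:
        thr = self.thresholds()  # raises on bad depth/mq combinations
        del thr
        if self.window < self.step or self.window % self.step:
            raise ValueError("window must be a multiple of step and >= step")
        if self.level not in (95, 99):
            raise ValueError("level must be 95 or 99")

    def thresholds(self) -> FilterThresholds:
        return FilterThresholds(
            min_depth=self.min_depth, max_depth=self.max_depth, min_mq=self.min_mq,
            min_gap=self.min_gap,
            min_parent_alt_fraction=self.min_parent_alt_fraction,
        )

    def genome_spec(self) -> sc.GenomeSpec:
        return sc.GenomeSpec(
            n_markers=self.n_markers, causal_chrom=self.causal_chrom,
            causal_pos=self.causal_pos, recomb_cm_per_mb=self.recomb_cm_per_mb,
            seed=self.seed,
        )


@dataclass
class PipelineResult:
    dataset: sc.SyntheticDataset
    filtered_records: list
    parental_records: list
    index_tables: dict
    windows: dict
    regions: dict
    overlap: list
    segregation: object
    lod_result: object
    narrow: object
    effects: list
    ranked: pd.DataFrame
    counts: dict


def _peak_region(regions: Sequence[qc.CandidateRegion],
                 windows: pd.DataFrame) -> qc.CandidateRegion | None:
    """The region whose windows carry the highest mean delta (the plot peak)."""
    best, best_score = None, -np.inf
    for r in regions:
        sub = windows[
            (windows["chrom"] == r.chrom)
            & (windows["end"] >= r.start)
            & (windows["start"] <= r.end)
        ]
        score = np.nanmax(sub["mean_delta"].to_numpy()) if len(sub) else -np.inf
        if score > best_score:
            best, best_score = r, score
    return best


def _bulk_sizes(cfg: PipelineConfig) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for rt, wt, n in cfg.bulk_pairs.values():
        sizes[rt] = n
        sizes[wt] = n
    return sizes


def run_in_memory(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage on in-memory objects (no files)."""
    cfg.validate()
    spec = cfg.genome_spec()
    ds = sc.simulate_dataset(
        spec, n_tetrads=cfg.n_tetrads, bulk_sizes=_bulk_sizes(cfg),
        mean_depth=cfg.mean_depth, sector_dist=cfg.sector_dist,
    )
    records = sc.bulk_to_records(ds.bulks)
    thr = cfg.thresholds()
    bulk_pool_names = [p for pair in cfg.bulk_pairs.values() for p in pair[:2]]
    filtered, removed = filter_variants(records, thr, depth_pools=bulk_pool_names)
    parental, removed_par = extract_parental_differences(
        records=filtered, thresholds=thr, parent_pool="P1",
        bulk_pools=bulk_pool_names,
    )

    counts = {
        "input_sites": len(records),
        "removed": dict(removed),
        "after_quality": len(filtered),
        "removed_parental": dict(removed_par),
        "parental_differences": len(parental),
    }

    chrom_lengths = dict(spec.chrom_lengths)
    index_tables, windows, regions = {}, {}, {}
    for pair_name, (rt, wt, n) in cfg.bulk_pairs.items():
        table = qc.snp_index_table(parental, rt, wt)
        ci = qc.NullDeltaCI(n_rt=n, n_wt=n, replicates=cfg.ci_replicates,
                            seed=cfg.ci_seed)
        table = qc.attach_ci(table, ci)
        win = qc.sliding_window_means(
            table, chrom_lengths, window=cfg.window, step=cfg.step,
            min_snps=cfg.min_snps_per_window,
        )
        index_tables[pair_name] = table
        windows[pair_name] = win
        regions[pair_name] = qc.call_regions(win, level=cfg.level,
                                             source=f"{rt}-{wt}")
    pair_names = list(cfg.bulk_pairs)
    overlap = regions[pair_names[0]]
    for name in pair_names[1:]:
        overlap = qc.intersect_pool_pairs(overlap, regions[name])

    # phenotype segregation check on the whole sector population
    n_wt = sum(1 for s in ds.samples if s.phenotype == "WT")
    n_rt = len(ds.samples) - n_wt
    segregation = chi_square_segregation(n_wt, n_rt)

    # sample partition: bulks already drew theirs; confirmation and KASP sets
    # come from the remainder where possible
    rng = np.random.default_rng([cfg.seed, 2_000_003])
    used = {sid for ids in ds.bulks.members.values() for sid in ids}
    rest = [s for s in ds.samples if s.sample_id not in used]
    rng.shuffle(rest)
    linkage_set = rest[: cfg.linkage_samples]
    kasp_set = rest[cfg.linkage_samples: cfg.linkage_samples + cfg.kasp_samples]
    if len(kasp_set) < cfg.kasp_samples:  # small populations: allow reuse
        kasp_set = (rest + [s for s in ds.samples if s.sample_id in used])[
            cfg.linkage_samples: cfg.linkage_samples + cfg.kasp_samples]

    lod_result = None
    if linkage_set:
        gm = GenotypeMatrix(
            genotypes=np.stack([s.genotype for s in linkage_set]),
            markers=ds.markers.assign(id=[f"M{i}" for i in range(len(ds.markers))]),
            phenotypes=np.array([1 if s.phenotype == "RT" else 0 for s in linkage_set]),
            sample_ids=[s.sample_id for s in linkage_set],
        )
        bins = screen_and_bin_markers(gm)
        lod_result = lod_scan(
            bins.matrix, permutations=cfg.lod_permutations, seed=cfg.seed,
            cm_per_mb=cfg.recomb_cm_per_mb,
        )
        counts["bin_markers"] = bins.matrix.genotypes.shape[1]

    # KASP-style narrowing inside the peak overlap region (the interval
    # carrying the strongest window-mean delta signal)
    narrow = None
    prior = _peak_region(overlap, windows[pair_names[-1]])
    if prior is not None and kasp_set:
        region_marker_idx = np.flatnonzero(
            ((ds.markers["chrom"] == prior.chrom)
             & (ds.markers["pos"] >= prior.start)
             & (ds.markers["pos"] <= prior.end)).to_numpy()
        )
        if region_marker_idx.size:
            targets = [
                prior.start + int(f * (prior.end - prior.start))
                for f in (0.125, 0.375, 0.625, 0.875)
            ][: cfg.kasp_markers]
            pos = ds.markers["pos"].to_numpy()[region_marker_idx]
            chosen = sorted({
                int(region_marker_idx[np.argmin(np.abs(pos - t))]) for t in targets
            })
            kasp_markers = (
                ds.markers.iloc[chosen][["chrom", "pos"]]
                .assign(id=[f"KASP{i + 1}" for i in range(len(chosen))])
                .reset_index(drop=True)
            )
            genotypes = np.stack([s.genotype[chosen] for s in kasp_set])
            phenotypes = np.array([1 if s.phenotype == "RT" else 0 for s in kasp_set])
            narrow = narrow_by_recombinants(
                kasp_markers, genotypes, phenotypes,
                [s.sample_id for s in kasp_set], prior,
            )

    final_region = narrow.region if narrow is not None else prior
    effects: list = []
    ranked = pd.DataFrame()
    if final_region is not None:
        region_records = [
            r for r in parental
            if r.chrom == final_region.chrom
            and final_region.start <= r.pos <= final_region.end
        ]
        effects = [
            classify_snp_effect(r.chrom, r.pos, r.ref, r.alt,
                                ds.annotation.genes, flank=cfg.flank)
            for r in region_records
        ]
        ranked = prioritize(final_region, ds.annotation.genes, effects,
                            ds.annotation.expression, cfg.deg_threshold)
        counts["region_snps"] = len(region_records)

    return PipelineResult(
        dataset=ds, filtered_records=filtered, parental_records=parental,
        index_tables=index_tables, windows=windows, regions=regions,
        overlap=overlap, segregation=segregation, lod_result=lod_result,
        narrow=narrow, effects=effects, ranked=ranked, counts=counts,
    )


def _write_truth(ds: sc.SyntheticDataset, outdir: Path) -> None:
    locus = pd.DataFrame(
        [{"chrom": ds.truth["causal_chrom"], "pos": ds.truth["causal_pos"],
          "gene_id": ds.truth["causal_gene_id"]}]
    )
    locus.to_csv(outdir / "truth_locus.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"sample_id": s.sample_id, "phenotype": s.phenotype,
          "blade_id": s.blade_id, "sector_count": s.sector_count}
         for s in ds.samples]
    ).to_csv(outdir / "truth_samples.tsv", sep="\t", index=False)
    ds.truth["planted_snps"].to_csv(outdir / "truth_snps.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": ds.truth["deg_gene_ids"]}).to_csv(
        outdir / "truth_degs.tsv", sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig, outdir: str | os.PathLike) -> PipelineResult:
    """Run all stages and write the report bundle under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = run_in_memory(cfg)
    ds = res.dataset
    chrom_lengths = dict(ds.spec.chrom_lengths)

    pio.write_vcf(sc.bulk_to_records(ds.bulks), outdir / "bulks.vcf",
                  chrom_lengths=chrom_lengths)
    pio.write_vcf(res.parental_records, outdir / "parental_filtered.vcf",
                  chrom_lengths=chrom_lengths)
    pio.write_gff3(ds.annotation.genes, outdir / "genes.gff3")
    pio.write_cds_fasta(ds.annotation.genes, outdir / "cds.fasta")
    ds.annotation.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    _write_truth(ds, outdir)

    for pair, table in res.index_tables.items():
        table.to_csv(outdir / f"snp_index_{pair}.tsv", sep="\t", index=False)
    for pair, win in res.windows.items():
        win.to_csv(outdir / f"windows_{pair}.tsv", sep="\t", index=False)
        qc.plot_delta(win, str(outdir / f"delta_{pair}.png"), level=cfg.level)
        pio.write_regions_tsv(res.regions[pair], outdir / f"regions_{pair}.tsv")
        pio.write_regions_bed(res.regions[pair], outdir / f"regions_{pair}.bed")
    pio.write_regions_tsv(res.overlap, outdir / "regions_overlap.tsv")
    if res.narrow is not None:
        pio.write_regions_tsv([res.narrow.region], outdir / "region_narrowed.tsv")
    if not res.ranked.empty:
        res.ranked.to_csv(outdir / "candidates_ranked.tsv", sep="\t", index=False)
    pd.DataFrame([vars(e) for e in res.effects]).to_csv(
        outdir / "snp_effects.tsv", sep="\t", index=False)

    log = {
        "config": asdict(cfg),
        "counts": res.counts,
        "segregation_chi2": res.segregation.chi2,
        "regions": {
            pair: [vars(r) for r in regs] for pair, regs in res.regions.items()
        },
        "overlap": [vars(r) for r in res.overlap],
        "narrowed": vars(res.narrow.region) if res.narrow is not None else None,
        "top_candidate": (res.ranked.iloc[0]["gene_id"] if not res.ranked.empty else None),
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    return res


def config_from_yaml(path: str | os.PathLike) -> PipelineConfig:
    """Load a config file; keys mirror the PipelineConfig fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg
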