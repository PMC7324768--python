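"""Meiosis, blade assembly and bulk sampling obey their genetic invariants."""

import numpy as np
import pandas as pd
import pytest

from pyroqtl.fine_mapping import chi_square_segregation
from pyroqtl.synthetic_cross import (
    GenomeSpec,
    assemble_population,
    build_bulks,
    sample_bulk,
    simulate_annotation_and_expression,
    simulate_parents,
    simulate_tetrad,
    simulate_tetrads,
)


def one_chrom_spec(n_markers=50, rate=4.37, length=10_000_000, seed=1):
    return GenomeSpec(
        chrom_lengths={"chr1": length}, n_markers=n_markers,
        causal_chrom="chr1", causal_pos=length // 2,
        recomb_cm_per_mb=rate, seed=seed,
    )


class TestSimulateParents:
    def test_markers_are_fixed_biallelic_differences(self, small_spec):
        markers = simulate_parents(small_spec)
        assert (markers["ref"] != markers["alt"]).all()
        for _, sub in markers.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing
            assert (sub["pos"].diff().dropna() > 0).all()
        assert markers["pos"].min() >= 1

    def test_deterministic_given_seed(self, small_spec):
        a = simulate_parents(small_spec)
        b = simulate_parents(small_spec)
        pd.testing.assert_frame_equal(a, b)

    def test_causal_locus_always_a_marker(self, small_spec):
        markers = simulate_parents(small_spec)
        hit = markers[(markers["chrom"] == small_spec.causal_chrom)
                      & (markers["pos"] == small_spec.causal_pos)]
        assert len(hit) == 1
        assert hit.iloc[0]["ref"] == "A" and hit.iloc[0]["alt"] == "C"

    def test_causal_position_off_chromosome_rejected(self):
        with pytest.raises(ValueError, match="off its chromosome"):
            GenomeSpec(chrom_lengths={"chr1": 1000}, causal_chrom="chr1",
                       causal_pos=2000)

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError, match="at least one marker"):
            GenomeSpec(n_markers=0)


class TestMeiosis:
    def test_two_to_two_segregation_every_marker(self, rng):
        spec = one_chrom_spec()
        markers = simulate_parents(spec, rng)
        for tetrad in simulate_tetrads(markers, spec, 50, rng):
            assert (tetrad.products.sum(axis=0) == 2).all()

    def test_zero_recombination_gives_parental_products(self, rng):
        spec = one_chrom_spec(rate=0.0)
        markers = simulate_parents(spec, rng)
        tetrad = simulate_tetrad(markers, spec, rng)
        sums = sorted(tetrad.products.sum(axis=1))
        m = len(markers)
        assert sums == [0, 0, m, m]  # two pure RZ, two pure HT products

    def test_sister_pairs_share_centromere_allele(self, rng):
        # products 0-1 and 2-3 descend from one centromere: at the first
        # marker (closest to the chromosome start) each pair is monomorphic
        spec = one_chrom_spec(rate=2.0)
        markers = simulate_parents(spec, rng)
        for tetrad in simulate_tetrads(markers, spec, 30, rng):
            first = tetrad.products[:, 0]
            assert first[0] == first[1] and first[2] == first[3]

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            one_chrom_spec(rate=-1.0)

    def test_recombinant_fraction_matches_haldane(self, rng):
        # two markers 50 cM apart: Haldane r = (1 - e^-1)/2 ~ 0.316
        length = 12_000_000
        spec = GenomeSpec(chrom_lengths={"chr1": length}, n_markers=2,
                          causal_chrom="chr1", causal_pos=1,
                          recomb_cm_per_mb=5.0, seed=1)
        markers = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [1_000_000, 11_000_000],
             "ref": ["A", "A"], "alt": ["C", "C"]}
        )
        n = 10_000
        fractions = np.empty(n)
        for i, tetrad in enumerate(simulate_tetrads(markers, spec, n, rng)):
            fractions[i] = (tetrad.products[:, 0] != tetrad.products[:, 1]).mean()
        expected = 0.5 * (1 - np.exp(-1.0))
        se = fractions.std(ddof=1) / np.sqrt(n)
        assert abs(fractions.mean() - expected) < 3 * se


class TestPopulation:
    def test_phenotype_follows_causal_allele(self, rng):
        spec = one_chrom_spec()
        markers = simulate_parents(spec, rng)
        tetrads = simulate_tetrads(markers, spec, 40, rng)
        causal = int(np.flatnonzero(
            (markers["pos"] == spec.causal_pos).to_numpy())[0])
        for s in assemble_population(tetrads, markers, spec, rng=rng):
            assert s.phenotype == ("RT" if s.genotype[causal] == 1 else "WT")

    def test_four_sector_blade_is_the_whole_tetrad(self, rng):
        spec = one_chrom_spec()
        markers = simulate_parents(spec, rng)
        tetrads = simulate_tetrads(markers, spec, 30, rng)
        samples = assemble_population(
            tetrads, markers, spec, sector_dist=(0, 0, 0, 1), rng=rng)
        by_blade: dict = {}
        for s in samples:
            by_blade.setdefault(s.blade_id, []).append(s)
        for i, (blade, sectors) in enumerate(sorted(by_blade.items())):
            assert len(sectors) == 4
            got = np.sort(np.stack([s.genotype for s in sectors]), axis=0)
            want = np.sort(tetrads[i].products, axis=0)
            assert (got == want).all()

    def test_sector_ratio_near_one_to_one(self, rng):
        spec = one_chrom_spec(n_markers=5)
        markers = simulate_parents(spec, rng)
        tetrads = simulate_tetrads(markers, spec, 4000, rng)
        samples = assemble_population(tetrads, markers, spec, rng=rng)
        n_rt = sum(s.phenotype == "RT" for s in samples)
        n = len(samples)
        assert n >= 10_000
        se = np.sqrt(n * 0.25)
        assert abs(n_rt - n / 2) < 3 * se

    def test_segregation_passes_chi_square_in_most_runs(self):
        spec = one_chrom_spec(n_markers=5)
        passed = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            markers = simulate_parents(spec, rng)
            tetrads = simulate_tetrads(markers, spec, 50, rng)
            samples = assemble_population(tetrads, markers, spec, rng=rng)
            n_rt = sum(s.phenotype == "RT" for s in samples)
            if not chi_square_segregation(len(samples) - n_rt, n_rt).significant:
                passed += 1
        assert passed >= 94

    def test_empty_tetrad_list_rejected(self, rng):
        spec = one_chrom_spec()
        markers = simulate_parents(spec, rng)
        with pytest.raises(ValueError, match="empty tetrad list"):
            assemble_population([], markers, spec, rng=rng)

    def test_bad_sector_distribution_rejected(self, rng):
        spec = one_chrom_spec()
        markers = simulate_parents(spec, rng)
        tetrads = simulate_tetrads(markers, spec, 5, rng)
        with pytest.raises(ValueError, match="summing to 1"):
            assemble_population(tetrads, markers, spec,
                                sector_dist=(0.5, 0.5, 0.5, 0.5), rng=rng)


@pytest.fixture(scope="module")
def population():
    spec = one_chrom_spec(n_markers=40, seed=5)
    rng = np.random.default_rng(5)
    markers = simulate_parents(spec, rng)
    tetrads = simulate_tetrads(markers, spec, 400, rng)
    samples = assemble_population(tetrads, markers, spec, rng=rng)
    causal = int(np.flatnonzero((markers["pos"] == spec.causal_pos).to_numpy())[0])
    return spec, markers, samples, causal


class TestBulks:
    def test_rt_bulk_fixed_at_causal_locus(self, population, rng):
        spec, markers, samples, causal = population
        _, alt, depth = sample_bulk(samples, "RT", 24, 80.0, rng)
        assert alt[causal] == depth[causal]
        _, alt_w, depth_w = sample_bulk(samples, "WT", 24, 80.0, rng)
        assert alt_w[causal] == 0

    def test_unlinked_marker_alt_fraction_near_half(self, population, rng):
        # pool both phenotypes (48 sectors): every marker is then at ~0.5
        spec, markers, samples, causal = population
        _, alt_r, d_r = sample_bulk(samples, "RT", 56, 200.0, rng)
        _, alt_w, d_w = sample_bulk(samples, "WT", 56, 200.0, rng)
        frac = (alt_r.sum() + alt_w.sum()) / (d_r.sum() + d_w.sum())
        n_reads = d_r.sum() + d_w.sum()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 56 / 40)

    def test_small_bulk_has_larger_frequency_variance(self, population):
        # binomial sampling of segregants: var(p_hat) = p(1-p)/n
        spec, markers, samples, causal = population
        var = {}
        for n in (8, 56):
            devs = []
            for seed in range(40):
                r = np.random.default_rng(seed)
                chosen, _, _ = sample_bulk(samples, "RT", n, 10.0, r)
                geno = np.stack([s.genotype for s in chosen])
                # markers far from the causal locus are ~Bernoulli(1/2)
                devs.extend((geno.mean(axis=0)[:5] - 0.5) ** 2)
            var[n] = np.mean(devs)
        assert var[8] > var[56]

    def test_insufficient_samples_raise(self, population, rng):
        spec, markers, samples, causal = population
        with pytest.raises(ValueError, match="need 100000"):
            sample_bulk(samples, "RT", 100_000, 50.0, rng)
        with pytest.raises(ValueError, match="mean depth"):
            sample_bulk(samples, "RT", 4, 0.0, rng)

    def test_build_bulks_counts_within_depth(self, population, rng):
        spec, markers, samples, causal = population
        bulks = build_bulks(samples, markers, {"RT8": 8, "WT8": 8},
                            mean_depth=50.0, rng=rng)
        for name, (alt, depth) in bulks.pools.items():
            assert (alt >= 0).all() and (alt <= depth).all()
        assert bulks.members["P1"] == []
        assert len(bulks.members["RT8"]) == 8


class TestAnnotation:
    def test_planted_gene_consistent_across_outputs(self, small_dataset):
        ann = small_dataset.annotation
        ids = {g.gene_id for g in ann.genes}
        assert ann.causal_gene_id in ids
        assert ann.causal_gene_id in set(ann.expression["gene_id"])
        assert ann.causal_gene_id in ann.deg_gene_ids
        snp = ann.planted_snps
        coding = snp[snp["effect_class"] == "coding_nonsynonymous"]
        assert len(coding) == 1
        assert coding.iloc[0]["gene_id"] == ann.causal_gene_id
        assert coding.iloc[0]["pos"] == small_dataset.spec.causal_pos

    def test_cds_lengths_divisible_by_three(self, small_dataset):
        for g in small_dataset.annotation.genes:
            assert g.cds_length % 3 == 0
            assert len(g.cds_seq) == g.cds_length

    def test_gene_models_non_overlapping(self, small_dataset):
        spans = sorted(g.span for g in small_dataset.annotation.genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2

    def test_region_too_small_rejected(self):
        spec = GenomeSpec(chrom_lengths={"chr1": 45_000_000}, n_markers=10,
                          causal_chrom="chr1", causal_pos=41_578_129)
        with pytest.raises(ValueError, match="too small"):
            simulate_annotation_and_expression(spec, n_genes=2000)

    def test_planted_degs_exceed_threshold(self, small_dataset):
        ann = small_dataset.annotation
        expr = ann.expression.set_index("gene_id")
        for gid in ann.deg_gene_ids:
            assert abs(expr.loc[gid, "log2fc"]) > 1.0
            assert expr.loc[gid, "detected"]
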