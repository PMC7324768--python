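# Methods

`pyroqtl` re-creates, as testable software, the mapping design used to
localize a single-locus color mutation in a haploid macroalga: a wild-type ×
mutant cross scored through ordered tetrads, bulked-segregant sequencing
(QTL-seq) of phenotype pools, linkage-style confirmation, recombinant-based
interval narrowing, and candidate-gene triage by variant effect and
differential expression. This note records the models, the parameters that
matter, and the choices made where the design was genuinely open.

## The cross and the tetrad model

Both parents are haploid: RZ (wild type, the reference genome) and HT (the
red mutant, carrying the alternate allele at every marker). Their zygote
undergoes meiosis during spore germination, producing an **ordered tetrad**
whose four haploid products develop into the 1–4 sectors of one chimeric
blade. Each sector is a single genotype; its phenotype (WT or RT) is read
directly from the allele it carries at the planted causal locus.

Meiosis uses Haldane's model: per chromosome the chiasma count is Poisson
with mean **2 × (map length in Morgans)** and breakpoints are uniform.  Each
chiasma joins one chromatid axis from each homologue (no chromatid
interference), and the four product molecules are traced through the
junction diagram segment by segment.  Two properties follow exactly and are
asserted in tests:

* **2:2 segregation** at every marker in every tetrad (allele conservation);
* the recombinant-product fraction between two markers d Morgans apart is
  **r = (1 − e^(−2d))/2** (Haldane's map function).

A subtlety worth recording: bookkeeping crossovers as content swaps between
evolving strands (rather than axis-occupancy tracking) looks equivalent but
under-produces recombinants when two chiasmata share a strand; the
simulation-vs-closed-form check caught a ~1-SD-per-replicate systematic
deficit during development. The axis-occupancy implementation matches the
closed form within Monte-Carlo error.

Sector counts per blade follow a configurable distribution over 1–4,
default **(0.1, 0.3, 0.3, 0.3)** — sectored blades more frequent than
unsectored, with no finer information available. Sectors are a uniform
subset of the tetrad's four products, so WT:RT segregates 1:1 in
expectation; the χ² goodness-of-fit test (below) passes at α = 0.05 in ≥94%
of seeded populations.

## Study conditions (generator defaults)

| parameter | default | note |
|---|---|---|
| chromosomes | chr1 45 Mb, chr2 35 Mb, chr3 28 Mb | three-chromosome, ~108 Mb genome |
| markers | 20,000 | fixed RZ/HT differences, uniform placement |
| causal locus | chr1:41,578,129 | distal end of chr1; always a marker (A→C) |
| recombination | 4.37 cM/Mb | ~472 cM total map over the genome |
| bulk pairs | 24+24 and 56+56 sectors | two independent phenotype pool pairs |
| mean depth | 100× per pool, Poisson | per-marker read depth |
| parent pool | HT, fixed alternate | reads = depth at every marker |

Bulk read counts are a two-stage binomial: the bulk's HT-allele frequency is
the mean over its pooled sectors' genotypes, and HT-supporting reads are
Binomial(depth, frequency) at Poisson(100×) depth.

The physical→genetic conversion used by the LOD-scan merge rule defaults to
the same 4.37 cM/Mb so the confirmation stage is consistent with the
generator; both are configurable.

## What the generator emulates — and what it does not

Emulated: fixed parental differences; meiotic linkage along three
chromosomes; chimeric blades; 1:1 phenotype segregation from one nuclear
locus; finite-bulk plus finite-depth sampling noise; gene models with one
planted non-synonymous coding change (a CAA→CCA, Gln331→Pro change in a
1,338-bp single-exon CDS), two planted regulatory-flank SNPs, planted
intergenic SNPs, and an expression table with 13 true DEGs (|log2FC| > 1,
the causal gene up ~6.5-fold) plus one silent (undetected) gene.

Not emulated: read-level errors, mapping artifacts, InDels, segmental
duplications, segregation distortion, non-uniform recombination landscapes
(real maps concentrate crossovers; the uniform map here makes candidate
regions wider than a real suppressed-recombination region would be),
multi-exon genes in the generator (the classifier itself handles them), and
expression noise structure. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated sampling
model — not that real libraries are free of alignment or calling artifacts.

## Variant filters

Sites must satisfy, in this order (removal counts are reported by first
failing rule): per-bulk depth within [4, 1000]; mapping quality ≥ 20;
distance to the nearest other site ≥ 5 bp. The adjacency rule removes
**both** members of a too-close pair — symmetric removal avoids order
dependence. Depth bounds are enforced on every pool entering the delta
statistic, since either bulk at low coverage corrupts the index. Parental
difference extraction keeps sites whose HT-parent alternate fraction is
≥ 0.9 (a haploid parent is effectively fixed; the margin tolerates sampling
noise) and which have non-zero coverage in both bulks. Multiallelic records
are rejected at parse time.

## The delta(SNP-index) scan

For each site, the SNP-index of a bulk is the fraction of reads carrying
the **HT (alternate)** allele, and delta = index(RT) − index(WT). With this
orientation the causal locus drives delta → +1; the orientation is a sign
convention only. Window means use a **1-Mb window sliding by 100 kb**,
anchored at position 1 (so window bounds have the form x00,001–y00,000);
windows with fewer than 3 sites are reported missing.

Null confidence bounds are simulated: under no QTL, each bulk of n sectors
has HT-allele count Binomial(n, ½), and the observed index re-samples that
frequency with Binomial(depth, p̂) reads. 10,000 replicates per observed
(depth_RT, depth_WT) pair give symmetric two-sided empirical 95% and 99%
quantiles; a window's bound is the mean of its member sites' bounds,
mirroring the averaging of the statistic itself. Implementation notes:

* each depth pair has its own seed-derived RNG stream, so bounds are
  independent of evaluation order and cacheable process-wide;
* replicates sharing a bulk allele count are sampled with one scalar-p
  binomial call (identical distribution, ~10× faster);
* significance is one-sided toward positive delta (the RT−WT contrast is
  directional by construction); the lower bound is retained for plotting;
* empirical-quantile coverage is self-consistent to within ±1% at the study
  depths; at very small bulk sizes (n ≤ ~4) the frequency distribution has
  so few atoms that CI width is not strictly monotone in depth — the
  monotonicity test grid therefore starts at n = 16.

Significant windows that overlap or abut merge into maximal candidate
regions; regions from the two bulk pairs are intersected (1-based,
inclusive). When the intersection has several intervals the pipeline keeps
the one carrying the highest window-mean delta (the plot peak).

## Confirmation and narrowing

*Segregation:* χ² = Σ(O−E)²/E against 1:1 with E = total/2, **no Yates
correction** (the uncorrected statistic reproduces the reference value 1.90
for 5,830:5,682; the corrected one gives 1.88), compared with 3.84 (df = 1,
α = 0.05).

*Binning and LOD scan:* markers with missing rate > 0.2 or MAF < 0.05 are
dropped; identical genotype columns (missing as its own symbol) form bin
markers represented by their leftmost member. The single-marker LOD for a
binary trait in haploids is LOD = log₁₀[θ̂^r (1−θ̂)^(n−r) / 0.5^n] with
θ̂ = r/n, r the count of alleles disagreeing with the phenotype-implied
allele among n informative samples (0⁰ = 1; missing calls excluded). The
genome-wide threshold is the 95th percentile of the max-LOD over 1,000
phenotype permutations; peaks closer than 10 cM merge keeping the higher;
support intervals are contiguous runs within 1.5 LOD of the peak.

*Recombinant narrowing:* at individually genotyped (KASP-style) markers, a
sample is recombinant iff its allele differs from its phenotype-implied
allele. Markers with zero recombinants cosegregate with the locus; the new
boundary on each side is the innermost recombinant-bearing marker's
position, kept **inside** the region (closed endpoint), so the narrowed
interval always contains the cosegregating block. A side with no
recombinant marker keeps the prior boundary; with no cosegregating marker
the prior region is returned unchanged. Narrowing is idempotent and nested.

## Candidate triage

SNPs in the final region are classified against the gene models: inside a
CDS, the reference and mutated codons are translated strand-aware with the
standard genetic code (residue index = ⌈CDS offset / 3⌉); within 1,000 bp
of a gene, upstream/downstream by strand (coding beats regulatory when both
apply; nearest gene wins among flanks); otherwise intergenic. DEGs are
detected genes with |log2FC| strictly > 1; genes with no detected
expression never qualify. Region genes rank: (1) DEG with a non-synonymous
coding SNP, (2) DEG with a regulatory SNP, (3) DEG only, (4) everything
else; ties break by |log2FC| descending, then position. Protein length
from a bare CDS length is length/3; from a sequence, one terminal stop is
trimmed first (both CDS-with-stop and CDS-without-stop conventions are
thereby supported). A 2^(−ΔΔCt) helper covers qPCR arithmetic.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive everywhere in memory and in
  VCF/GFF3/TSV; BED output is 0-based half-open, converted only at the I/O
  boundary and round-tripped exactly.
* All randomness flows from explicit seeds; the null-CI simulator has its
  own seed (default 1) so CI bounds are reproducible independently of the
  data seed. Run logs record every seed, threshold and per-stage count, and
  identical configurations produce byte-identical TSV outputs.
* Zero-depth sites are undefined for the index and must be filtered first
  (enforced); both-counts-zero segregation tests, empty tetrad lists,
  unsorted or duplicated sites, multiallelic records, ambiguous bases and
  CDS/reference mismatches raise immediately with the offending position.

## Replicated studies and problem sizes

The package's calibration studies (also run by `scripts/acceptance.py`) use
50 full-pipeline replicates at the default study conditions above, 10,000
null-CI replicates, and 10,000 tetrads for the map-function check. Observed
under these conditions: null-CI coverage within 1% of nominal; the planted
locus inside the 56-pair 95% region, and the planted gene ranked first, in
well over 90% of replicates. Because the uniform recombination map spreads
linkage widely, the called regions are broader (tens of Mb) than a real
landscape with locally suppressed recombination would give; containment of
the locus, not region width, is the calibrated claim.

## Known limitations

* Uniform recombination and marker placement — no hotspots, no
  marker-desert chromosome ends.
* The LOD scan is a single-marker binomial-likelihood scan, not interval
  mapping: positions between markers are not scored and no covariates are
  supported.
* The two bulk pairs are drawn from one simulated population, so their
  errors are not fully independent (they share meioses), slightly
  understating the benefit of intersecting pairs relative to truly
  independent populations.
* The effect classifier assumes the CDS sequence provided matches the
  reference genome at the variant site and rejects otherwise; it does not
  re-derive CDS from a genome FASTA.
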