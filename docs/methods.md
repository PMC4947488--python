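# Methods

## Copy-number model

Read depth at a base is modelled as proportional to the local chromosome
copy number. The estimator works entirely in medians to be robust to
depth outliers: for gene *g*, `m_g = median(depth over the gene's
unmasked bases)`; the sample level is `M = median over all genes of
m_g`; normalised coverage is `m_g / M`; the chromosome statistic is the
median of its genes' normalised values; absolute copies are
`chromosome median × f`, where the ploidy factor `f = DNA content (n) /
2` comes from flow cytometry. Normalisation erases absolute depth, so a
balanced genome always sits at normalised 1.0 regardless of its true
ploidy; the factor restores the absolute scale. In an allodiploid
(content 2n) the typical chromosome carries one copy per subgenome and
`f = 1` maps 1.0 → 1; in an allotetraploid (4n) the typical chromosome
carries two copies and `f = 2` maps 1.0 → 2.

**Median convention.** All medians are interpolated (mean of the two
central order statistics for even counts). This matters for the mixed
allotriploid: with the 2-copy and 1-copy classes contributing equal
numbers of genes, the interpolated sample median lands exactly halfway
between the two depth levels (1.5 × per-copy depth), so normalised
values are 4/3 and 2/3 and the 1.5 factor maps them to 2.0 and 1.0. A
lower-order-statistic convention would collapse onto one class and break
the calibration.

**Rounding and uncertainty.** Integer calls round half away from zero.
Raw values further than 0.35 from the nearest integer are flagged
`uncertain` — the signature of chimeric or mosaic chromosomes whose
true per-base copy number is non-constant — but still reported, since
suppressing them would hide exactly the interesting cases.

**Masking and alignment filters.** Repeat masking is an optional BED
input (default none); fully masked genes are dropped and reported. A
minimum-MAPQ filter belongs to alignment ingestion and is out of scope
here: synthetic depth tracks are taken as pre-filtered.

## Zygosity corroboration

SNP records carry allele depths and flank-read support. Records with
fewer than 5 reads on either flank are discarded (threshold inclusive:
exactly 5 on both flanks survives). Classification uses the alt-read
fraction: heterozygous in [0.25, 0.75], homozygous at ≥ 0.90, else
ambiguous (tallied, excluded from summaries). The bands quantify
"equal proportions" / "only the alternate allele" and are configurable;
the gap is deliberate — forcing borderline records into a class would
contaminate both.

Corroboration per chromosome: ≥ 20 informative (het+hom) SNPs required;
het fraction ≥ 0.8 ⇒ "≥2 copies", ≤ 0.05 ⇒ "1 copy", else indeterminate.
The heterozygosity-density ratio between subgenomes is computed only
over chromosomes corroborated ≥ 2 copies, because het sites are
unobservable on single-copy chromosomes and including their length
would deflate the density. A zero minor-subgenome density returns an
infinite sentinel with a flag rather than an error.

**Chimera detection** is windowed majority vote: consecutive windows of
25 informative SNPs (trailing remainder ignored), each labelled
het- or hom-dominant at the 0.5 mark, merged into runs; a chimera needs
at least two runs of ≥ 3 windows with disagreeing states, and the
breakpoint is the midpoint between the flanking SNPs of adjacent runs.
A two-state HMM was considered and rejected: the signal is effectively
binary with very low misclassification at realistic depth, and the
windowed vote has an interpretable resolution bound (≈ window span;
at 1 SNP/kb and 25-SNP windows, a few tens of kb).

## Mitochondrial inheritance

Uniparental by assumption: the call is `Scer` if its mitochondrial
contig's mean depth is ≥ 4× the other's, symmetrically `Seub`, else
`unresolved` (including 0 vs 0). The 4× default is deliberately
conservative — observed inheritance in such hybrids is near-exclusive,
so any ambiguous ratio more likely reflects cross-mapping or barcode
hopping than genuine heteroplasmy, which this caller does not model.

## Quantitative statistics

qPCR efficiency from the standard-curve slope, `E = 10^(−1/m)` (perfect
doubling at m ≈ −3.32); relative ratios by the efficiency-corrected
(Pfaffl) formula. Expression–aroma fits are ordinary least squares of
compound concentration on the maximum transcription of the two parental
orthologues plus intercept, per (compound, gene) pair, with an ANOVA
F-test and per-coefficient t-tests; coefficients at p > 0.05 are marked
NS. No multiple-testing correction is applied across pairs by default
(a Benjamini–Hochberg pass is easy to add downstream); predictors are
fitted on the raw signal scale, which is why coefficients land around
10⁻⁴ for signals in the thousands. The copy-number correlation first
standardizes each gene's signals to zero mean and unit variance across
strains (sample sd), then pools all (strain, gene) pairs for a Pearson
correlation against integer copies. z-score matrices use the sample
(n−1) standard deviation, matching the default of mainstream statistics
environments; constant compound columns yield all-zero rows with a flag
(a tolerance of 1e-12 relative to the column mean absorbs accumulated
floating-point rounding in "constant" columns).

## Synthetic data generator

The generator emulates the downstream *shapes* of a sequencing
experiment, not reads: per-base depth is drawn i.i.d. negative binomial
with mean `copies × per_copy_depth` and size parameter `r`
(variance = μ + μ²/r). The default `r = μ` gives variance = 2 × mean, a
mild overdispersion typical of short-read depth; larger `r` approaches
Poisson. SNP sites arrive as a Poisson process per subgenome at
configurable densities (defaults: Scer 2×10⁻³/bp heterozygosity-capable
and Seub 10⁻⁵/bp — a 200:1 asymmetry — plus 5×10⁻⁵/bp fixed differences
on both); het-capable sites emit heterozygous records
(alt ~ Binomial(DP, 0.5)) on ≥ 2-copy chromosomes and homozygous records
on single-copy ones; homozygous draws use a 1 % per-read error
(alt ≈ 0.99), so classification bands are actually exercised. Flank
counts are Binomial(DP, 149/150): under 150 bp reads, a covering read
fails to extend strictly left of a site only when it starts exactly on
it. Mitochondrial background on the non-inherited contig is Poisson at
0.2 reads/base, forcing callers to use a ratio rather than mere
presence. Coordinates are 0-based half-open internally and in BED
output; depth TSVs and variant positions are 1-based (samtools-depth /
VCF dialects). All draws run through per-stage, per-chromosome seed
sequences, so outputs are byte-reproducible and order-independent.

What the generator does **not** model: sequencing error in depth,
GC/mappability bias, indels or structural variants beyond whole-
chromosome copy change and a single zygosity breakpoint, linked reads,
and real FreeBayes/CNVnator artefacts. Passing recovery tests therefore
demonstrates the estimators are correct under the stated noise model —
not that they are robust to every bias of real libraries; the MAPQ and
repeat-mask hooks exist for that when real alignments are ingested.

## Study conditions used in tests and analyses

Desk-scale archetypes mirror the three hybrid classes: allotetraploid
(11 chromosomes, all 2-copy, one Seub chromosome reduced to 1),
allotriploid (10 chromosomes: 5 Scer at 2, one Scer and 4 Seub at 1),
allodiploid (12 chromosomes, all 1-copy, one Scer chromosome lost) — 33
chromosomes in total, each 100 kb with 25 genes of 2 kb, at 25× per-copy
depth. The 100 kb length is a deliberate scale-down from real yeast
chromosomes (0.2–1.5 Mb): with 25 genes the chromosome-median estimator
already has the sampling behaviour that matters, while a full sweep of
archetypes × 20 seeds stays fast. The heterozygosity-ratio experiment
uses two 20 Mb chromosomes at heterozygosity densities 2.5×10⁻² (Scer)
vs 1.25×10⁻⁴ (Seub) per bp — 200:1 — sized so the minor subgenome contributes
≥ 2000 sites and the Poisson sampling error on the ratio (≈ 2 %) is far
inside the 20 % recovery tolerance. Chimera experiments use 1 Mb
chromosomes at 1 SNP/kb with a breakpoint at 500 kb.

## Known limitations

- The corroboration thresholds (0.8 / 0.05 het fraction) and chimera
  stability parameters are heuristics chosen for clear two-state
  signals; heavily mosaic chromosomes will surface as "indeterminate"
  or "uncertain" rather than resolved structures.
- Sub-chromosomal CNV segmentation, GC correction and mappability
  tracks are out of scope; the estimator calls whole chromosomes.
- The regression module fits each (compound, gene) pair independently;
  with many pairs, users should enable a multiple-testing correction.
- Real-data ingestion accepts pre-computed depth TSVs and variant
  tables; running aligners or variant callers is outside the package.
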