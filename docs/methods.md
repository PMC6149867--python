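# Methods

This note records the models, the defaults and the judgement calls behind
`dioica`, in enough detail to audit or re-derive every number the package
prints.

## Differential expression model

Counts are modelled per gene and sample as negative binomial with mean μ
and dispersion α under the mean–dispersion parametrisation
Var = μ + α·μ². Library depth is removed with median-of-ratios size
factors: each gene with strictly positive counts in every sample
contributes its geometric mean as a pseudo-reference, and a sample's
factor is the median over those genes of count/reference. When no such
gene exists (heavily zero-inflated matrices) an explicit
`allow_pseudo_reference` flag switches to geometric means over the
positive entries only; the default is to fail loudly, since silent
fallback changes the estimator. Note that scaling one library by c moves
all factors through the geometric reference (the scaled sample's factor by
c^((S−1)/S), the rest by c^(−1/S)); only factor *ratios* scale exactly by
c, which is what normalisation consumes, and log₂FC of every gene
expressed in both sexes is exactly invariant.

The two-group test is a Wald test on log(mean_M) − log(mean_F) of
normalised counts. The delta method gives
Var(log m̄_k) ≈ (μ_k + α μ_k²)/(n_k μ_k²) per sex. Dispersion is estimated
per gene by method of moments within each sex, α̂_k = (s_k² − m̄_k)/m̄_k²,
pooled across the two sexes by degrees of freedom and floored at 10⁻⁸.
With three replicates this estimate has essentially two degrees of freedom
per sex and is far too noisy to plug into a normal-reference Wald test
(measured null type-I error ≈ 0.12 at nominal 0.05). The package therefore
shares information across genes the way the early NB DE tools did: the
per-gene estimate is floored at the **median of the per-gene estimates
over all genes expressed in both sexes**. Taking the larger of the
per-gene and shared values never shrinks a gene's variance below its own
evidence, so the statistic can be referred to a standard normal and stays
calibrated: on an all-null 10,000-gene 3v3 simulation at μ = 100,
α = 0.05 the fraction of p < 0.05 is ≈ 0.049, and the far tail is
conservative (p < 0.003 realised at ≈ 0.0005), which keeps the realised
FDR of BH selection near 1%. A Student-t reference with pooled degrees of
freedom was evaluated instead and rejected: it calibrates the 0.05 level
but its heavy tail destroys power exactly where the pipeline needs it —
structural-zero (sex-specific) genes sit near p_adj ≈ 0.08 and would be
missed.

Fold changes are log₂(m̄_M/m̄_F); when either sex's mean is zero both
means get a pseudo-count of 0.5 so the estimate stays finite (these values
are reported, not tested against, so the pseudo-count's scale-dependence
is cosmetic). All-zero genes are defined as null (p = 1, log₂FC = 0).
Benjamini–Hochberg adjustment is the standard step-up with running-minimum
monotonicity, ties broken by stable order (which cannot affect values).

Classification follows the printed operators of the study design this
package targets: biased iff p_adj < 0.05 (strict) and |log₂FC| ≥ 1
(inclusive); male-biased means up-regulated in males. Sex-specific calls
are made **within** the biased set: zero raw counts in every replicate of
one sex and mean FPKM strictly above 0.03 in the other. A
`floor_mode="all"` variant applies the floor to every replicate instead of
the mean, since published criteria of this form rarely say which was
meant. FPKM uses column sums of the count matrix as library sizes: true
mapped-fragment totals are not recoverable downstream of assembly, and the
ratio to any consistent total is what the floor effectively thresholds.

Sample clustering uses average linkage on 1 − Pearson correlation between
sample profiles of log₂(FPKM+1) over the biased genes, cut into two
groups. (Tools billed as "K-means heatmaps" in this literature default to
hierarchical clustering; the hierarchical form is deterministic and
testable, which is why it is used here.) A constant expression profile
would make the correlation undefined; such samples are treated as
uncorrelated with everything rather than crashing the run.

## Sex-segregating SNP filter

Genotype calls are one allele per (gene, position, individual) with a read
depth. The filter is the conjunction of three criteria — depth ≥ 5
(inclusive) in **every** individual, polymorphism, and within-sex fixation
with between-sex difference — of which the third implies the second at
site level, so the implementation checks fixation directly; the
exhaustive-enumeration tests confirm the equivalence over all biallelic
assignments. Heterozygous and missing genotypes make an individual
uncallable, and any uncallable individual makes the position ineligible,
because the criteria quantify over each individual. This renders the two
documented heterozygote policies (`nocall` and `fail-site`) extensionally
identical; both are accepted so configurations can state their intent.
Depth is taken as the VCF's FORMAT/DP, i.e. post-deduplication coverage
when the caller was run on deduplicated alignments. Positions are 1-based
along the transcript, 5′→3′, used exactly as the VCF POS.

For context in reports, `segregation_null_rate(n_M, n_F)` gives the exact
probability 2/(2^(n_M+n_F) − 2) that a random polymorphic biallelic
assignment (all assignments equally likely) splits along sex — with 3+3
individuals, ≈ 3.2%, which is why the filter needs the depth and fixation
criteria rather than polymorphism alone.

## SNP spectrum and sequence summaries

Substitutions are typed by the unordered pair: C/T and A/G are
transitions, the other four pairs transversions; orientation (ref vs alt)
never matters. Densities are SNPs per kilobase with the total assembled
transcript length as denominator, computed at full precision and rounded
half-up to two decimals only in report tables. Codon positions within an
annotated CDS (1-based inclusive bounds, frame 0) are
1 + (pos − cds_start) mod 3; synonymy translates the reference and
substituted codons under the standard genetic code with stop as its own
product, and only the annotated forward frame is evaluated (assembled
unigenes are orientation-resolved transcripts). N50 is the largest length
L such that sequences of length ≥ L cover at least half the total bases.
FASTQ QC reports the percentage of bases at Phred ≥ 20 and ≥ 30, GC among
unambiguous bases only, and the mean per-base error probability
10^(−Q/10) in percent.

## Enrichment

The probability weighting function bins genes into 20 length quantiles
(rank-based, so ties cannot unbalance bins) and assigns each gene its
bin's DE fraction, clipped to (10⁻⁶, 1−10⁻⁶). This is a deliberately
simple, fully testable stand-in for the monotone spline fit of the GO
tooling it approximates; with a handful of thousands of genes the binned
estimate is already stable (flat within 3 binomial SE when DE is
length-independent).

The Wallenius non-central hypergeometric tail is computed **exactly** by
dynamic programming over the sequential biased-draw process that defines
the distribution: drawing the n DE genes one at a time, the next draw hits
the category of size K with probability ω·r/(ω·r + w), r and w the
remaining category and non-category genes. The DP is O(n·min(n,K)),
exact to float rounding (it matches an independent implementation to
4·10⁻¹¹ and reduces to the central hypergeometric at ω = 1 to better than
10⁻¹²), so no large-N approximation is needed at the scales the package
targets; inputs beyond ~10⁷ DP cells would simply be slow rather than
wrong. Only over-representation (upper tail) is tested. Odds are the mean
PWF weight inside the category over the mean outside. Across categories,
p-values get BH adjustment reported as q-values — an exact discrete test
is conservative when the attainable p-grid is coarse (small categories),
which is a property of exactness, not miscalibration; the calibration
tests use categories of 100 genes where the realised level is ≈ 0.045.
The universe is the set of count-matrix genes that carry an annotation.

## Synthetic data generator

The generator emulates the study design this toolkit grew out of: six
individuals (3 per sex, one library each), an assembled transcriptome,
NB counts, and GATK-style biallelic genotype calls. Defaults:

| parameter | default | meaning |
|---|---|---|
| n_genes | 2,000 | transcriptome scaled down from ~1.5·10⁵ |
| n_males / n_females | 3 / 3 | replicates per sex |
| gene_length_range | 200–2,000 bp | uniform; mean ≈ 1.1 kb, like a short-read assembly |
| baseline_mean | 100 counts | expressed-gene NB mean |
| dispersion | 0.05 | α in Var = μ + αμ²; an **assumption** (the emulated studies report none), moderate for replicated plant tissue |
| planted_log2fc | 5 | biased genes; split symmetrically, μ·2^(±2.5) |
| n_male_biased / n_female_biased | 33 / 12 | biased but not specific |
| n_male_specific / n_female_specific | 40 / 31 | structural zeros in the silent sex |
| n_snp_sites / n_sex_segregating | 60 / 9 | remaining sites: ⅔ non-segregating decoys, ⅓ depth-failing |
| depth_mean | 20 | Poisson per-sample depth, floored at 5 |
| read simulation | 200 × 100 bp, GC 0.5, Q 30–40 | QC-stage inputs only |

The planted classes total 116 differential genes — 73 male-side of which
40 specific, 43 female-side of which 31 specific — the headline structure
of the emulated experiment. Sex-specific genes are structural zeros (the
silent sex's counts are identically 0, not sampled), so the observed-zero
criterion is exactly satisfiable. Biased genes split the planted fold
change geometrically so the expected log-ratio equals the planted value.
Segregating sites are fixed within sex with depth ≥ 5 everywhere; decoy
sites are rejection-sampled polymorphic patterns that do not split by sex;
depth-failing sites carry a perfect segregation pattern but sub-threshold
depth in ≥ 1 individual, exercising the depth criterion specifically. The
VCF REF allele is the transcript base at the site, so FASTA and VCF are
mutually consistent. One global seed fans out into fixed per-stage
substreams (`numpy` `default_rng([seed, stage])`), making stages
independently regenerable and all outputs byte-identical across runs.

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about real data: mean–dispersion trends and
outlier dispersions, GC/positional coverage bias, misassembly and
multi-mapping artefacts, allele-specific expression, indels and
multi-allelic sites, genotyping error, and correlated library effects.
The recovery results should be read as "the implementation applies its
stated criteria exactly", not as field performance estimates.

## Numerical and degenerate-input conventions

Dispersion floor 10⁻⁸; PWF clip 10⁻⁶; fold-change pseudo-count 0.5;
report rounding half-up at 2 decimals only at the render layer; BH capped
at 1; empty call sets, empty site sets and zero-DEG runs produce empty
tables rather than errors, while contract violations (negative counts,
p ∉ [0,1], unknown samples, reference-base mismatches, zero-length genes)
raise typed exceptions naming the offender. Threshold comparisons follow
the printed operators: p_adj < α strict, FPKM > floor strict, |log₂FC| ≥
threshold inclusive, depth ≥ 5 inclusive.

## Known limitations

Two-group designs only (no covariates or batch terms); no shrinkage of
fold changes; no exact NB test; the PWF is binned rather than splined; GO
term ancestry is not propagated; the segregation filter has no tolerance
mode for one discordant individual (deliberate — the published criteria
are exact); FPKM library sizes are count-matrix column sums, not mapped
totals. Problem sizes in the test suite (10⁴-gene null, 2·10³-category
calibration, 20-seed recovery) were chosen so the full suite runs in
about half a minute while keeping Monte-Carlo standard errors well inside
the asserted bands.
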