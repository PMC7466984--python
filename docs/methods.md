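# Methods

This note records the statistical model behind each pipeline stage, the
generator's data model, the defaults and why they were chosen, and what
passing the test suite does and does not establish about real data.

## Estimators

**Mutation-rate estimator.** Throughout, "mutation rate" means SNP
density: the number of distinct eligible sites (or bases) carrying a rare
SNP divided by the number of eligible sites (bases). Rare SNPs
(AF < 0.1%, quality exactly 100, autosomal, biallelic, non-structural)
proxy de novo germline mutations; rarity minimises the footprint of
selection and biased gene conversion. Multiple catalog records at one CpG
site — including the two cytosines of the same dinucleotide — count once,
so a density is per-site probability mass and cannot exceed 1.

**Mutation types.** Each SNP is classified from the reference context
only: CpG context iff the reference C is followed by G (or the reference
G is preceded by C), with purine-strand changes collapsed onto the
pyrimidine strand (G>A ≡ C>T, …), yielding three CpG and six non-CpG
types. Positions whose required neighbour is N or off the chromosome end
are counted as unclassified rather than guessed. "Quality of exactly
100" follows the convention of the population call set the pipeline
targets; `--min-qual`-style config exists for other call sets.

**Methylation level and call.** Level = methylated reads / total reads at
a cytosine with ≥ 5 reads. "Methylated" is a one-sided exact binomial
test against a background rate p₀ (alternative: greater), BH-corrected
across the sites of a stage; a site failing the test is "unmethylated".
p₀ = 0.01 (typical bisulfite non-conversion + sequencing error) and
α = 0.05 are config keys; the test names only the procedure, so these are
the package's own defaults. Consequence, visible in real and synthetic
data alike: truly low-level sites land in "unmethylated", which can raise
that category's density above the 0–20% bin.

**Bins and states.** Methylated sites are binned left-closed/right-open
([0,0.2), …, [0.8,1.0] with the top bin closed) so the bins partition
[0,1]. The three-state code is H (≥ 0.7), U (< 0.2), M otherwise. The
bin-trend statistic is Pearson's r of the five bin densities against bin
midpoints (0.1 … 0.9) — the least-structured choice of x-values, also a
config key. The methylated/unmethylated contrast is a 2×2 chi-squared
test with Yates continuity correction (toggleable), matching common
statistical-software defaults.

**Common sites and patterns.** To remove coverage bias between samples,
pattern- and regression-level analyses use only sites covered ≥ 5× in all
13 stages. A site's dynamic pattern is the 13-character H/M/U string in
the fixed stage order (sperm, oocyte, 8cell, morula, ICM, PGC7wm,
PGC10wm, PGC10wf, PGC11wm, PGC11wf, PGC13wm, PGC17wf, PGC19wm); patterns
with ≥ 10 CpG SNPs are ranked by density, ties broken by descending site
count then lexicographic code (determinism). Pattern SNP counts use all
three CpG types, consistent with the site-level numerator.

**Regression.** The per-site model is a linear probability model: OLS of
the 0/1 mutation indicator on the 13 raw stage levels with an intercept
and classical standard errors. OLS (not logistic) is the estimand the
coefficient table targets; logistic is available as an option. Stepwise
selection starts from the full model and greedily drops/adds single terms
("both" direction) while AIC falls; the internal fast path computes
Gaussian AIC from least-squares RSS and is tested to equal the
statsmodels value exactly.

**Regions and tiles.** Raw annotation tracks overlap, but the analysis
classes must not, so a precedence order is applied: promoters (strand-aware
TSS −1000/+200) first; CGIs minus promoters; enhancers minus promoters and
CGIs; gene bodies (intragenic = exon ∪ intron) minus all of the above;
intergenic = complement of everything annotated; repeats subtracted from
every other class *last*. Each class's merged intervals are cut into 1-kb
tiles from each interval start; terminal partial tiles are kept (a
`drop_partial` flag exists) and all tiles face the ≥ 5-CpG floor.
Tile statistics: CpG C>T density = CpG C>T SNPs over C/G bases at CpG
sites (a CpG straddling a tile edge contributes only its in-tile base);
non-CpG C>T density analogously over non-CpG C/G bases; methylation is the
read-weighted level (Σ methylated / Σ total), not the mean of site ratios.
Correlations are Spearman with average ranks, reported per class × stage ×
measure; groups under 10 tiles (3 in chromosomal mode) are reported as
missing rather than estimated.

**Promoter proxies.** CpG O/E uses the canonical
(N<sub>CpG</sub>·L)/(N<sub>C</sub>·N<sub>G</sub>) form with N bases
excluded from all counts; an L−1 denominator variant is a config option.
Promoter SNP density counts all three CpG types by default (C>T-only is
an option). Expression is used strictly as a *negative correlate* of
promoter methylation — no methylation values are imputed from it. Note
the sign asymmetry: methylation raises contemporary SNP density but
lowers CpG O/E (historical CpG loss), so germline tissues concentrate at
the negative end of the expression/density ranking and the positive end
of the expression/O-E ranking.

## The generator

The generator defines the study conditions for every stochastic test.

*Genome.* I.i.d. background (A/T 0.3, C/G 0.2 each); CpG depletion is
imposed by thinning CG dinucleotides — the C of a removed CG becomes T,
mimicking historical deamination — with the keep-probability solved from
the target background CpG rate (default 0.01/bp, roughly human). CpG
islands are undepleted 2-kb blocks (≈ 4% CpG), one per 100-kb annotation
cassette. Annotations are laid out deterministically on that cassette:
six genes (both strands; one with a CGI promoter), enhancers deliberately
overlapping a promoter and an island, repeats inside and outside genes —
so every disjointification rule is exercised by construction.

*Methylomes.* Latent levels have exact Beta(a_s, b_s) marginals per stage
(mean·c, (1−mean)·c with concentration c = 2), coupled across stages by a
Gaussian copula with one site factor (share 0.6). The site factor itself
mixes a 2-kb methylation-domain block component (half its variance) with
an independent per-site part — regional smoothness is a defining feature
of real methylomes and is what the tile-level analysis measures — and
island CpGs receive a −2 shift (hypomethylated CGIs). Stage means follow
the known trajectory: sperm 0.85, oocyte 0.50 down to 0.15 at the
PGC10–11-week trough, partially recovering by week 19. Reads are
Binomial(depth, m(1−ε)+(1−m)ε) at Poisson depth (default λ = 15,
ε = 0.005); low-depth sites are emitted so the ≥ 5-read filter is
exercised.

*Variants.* A CpG site mutates with probability b₀ + Σ β_s·m_is (default
b₀ = 0.01, β_sperm = 0.15, others 0), reported on either cytosine of the
dinucleotide with equal chance; C>T with probability 0.8, else C>A/C>G
equally. Non-CpG C/G and T/A bases mutate at a flat 10⁻³ with fixed type
splits. Allele frequencies are uniform below 0.1% with a 10% contamination
above it, 5% of records get QUAL 60, and ~2.5% indel/multi-allelic/symbolic
records are injected — so every filter rule fires on default output.

*Expression.* expression(g, t) = c_t · promoterMethylation(g) + N(0, 0.1),
with c_t = −0.5 for the 20 germline tissues (primordial/male/female germ)
and 0 for the 20 somatic tissues across 7 classes. True promoter
methylation is the latent level averaged over promoter CpGs and stages.

*Recovery preset.* Parameter-recovery studies use a clean preset: 10 Mb,
deep coverage (λ = 100, ε = 0.001) and no catalog contamination, so the
OLS estimand equals the generator's β. Two effects would otherwise bias
the comparison against truth and are real phenomena, not artefacts:
read-sampling noise on the predictors attenuates OLS slopes
(errors-in-variables), and filter-removed true variants thin the response.
The recovery regression therefore builds its design from the generator's
latent levels (that is what the ground-truth object is for), while the
observed-data path is validated by the monotone-bin, pattern and regional
checks, and the default shallow-coverage study documents the attenuation
(β̂ ≈ 0.09 at 15×).

*What the generator does not emulate* — and hence what passing tests do
not show about real data: realistic base composition and repeat content,
mutation-type proportions (CpG types are deliberately over-represented),
spatial variant clustering, selection and biased gene conversion,
sex-chromosome biology, bimodal near-0/1 methylation at regulatory
elements beyond the island shift, and between-stage coverage differences
beyond Poisson depth.

## Problem sizes and determinism

Default study: 1 chromosome × 1 Mb (~10,500 CpGs, ~2,400 variant
records), seconds end to end. Recovery studies: 10 Mb (~106,000 CpGs,
~24,000 clean SNPs), ~10 s per replicate; seeded replicate sets use 20
fixed seeds. These sizes make the stochastic checks sharp (binomial noise
well below the planted effects) while keeping the whole suite in a few
minutes. All randomness flows from a single integer seed through
`numpy.random.default_rng`; file writers emit no timestamps, so reruns
are byte-identical, and the pipeline records a manifest (config hash,
input checksums, package version) with every run.

## Known limitations

- The linear probability model can in principle predict outside [0,1];
  with the default effect sizes it does not, and OLS is the estimand of
  record (logistic is an option, not the default).
- Classical OLS standard errors ignore the binomial heteroskedasticity of
  a 0/1 response; at the recovery effect sizes the CI coverage loss is
  negligible (verified empirically by the 20-seed coverage test).
- Greedy stepwise AIC is path-dependent by construction; it is
  deterministic given a design but is not guaranteed to find the global
  AIC optimum.
- The enhancer track is an input; the package does not call enhancers,
  normalise methylomes across stages, or impute uncovered sites.
- Promoter CpG O/E uses the full promoter sequence including any CGI;
  no GC-content correction is applied beyond the O/E form itself.
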