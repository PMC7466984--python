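# methmut

Does the dynamic DNA methylome of the human germline shape where germline
point mutations arise? Spontaneous deamination of 5-methylcytosine turns
methylated CpG into TpG, so CpG mutability should track methylation — but
methylation is reprogrammed twice during germline development (after
fertilisation and again in primordial germ cells), and different stages may
contribute differently to the mutation spectrum we inherit.

`methmut` is an analysis pipeline that quantifies this link at three scales,
using rare population variants (allele frequency < 0.1%, a standard proxy
for de novo germline mutations) and per-cytosine whole-genome bisulfite
sequencing (WGBS) methylomes across 13 germline developmental stages
(sperm, oocyte, 8-cell embryo, morula, ICM, and primordial germ cells from
gestational weeks 7–19):

- **site level** — SNP density at CpG sites stratified by methylation
  state (binomial-test methylation calls, five level bins), with the
  bin-trend Pearson correlation and a methylated-vs-unmethylated
  chi-squared test;
- **pattern level** — each common CpG site gets a 13-character H/M/U code
  (its *dynamic methylation pattern*, H: level ≥ 70%, U: < 20%); patterns
  with ≥ 10 CpG SNPs are ranked by SNP density;
- **regression** — per-site multiple linear regression of the 0/1 mutation
  indicator on the 13 stage levels, y<sub>i</sub> = β₀ + Σ<sub>s</sub>
  β<sub>s</sub>·m<sub>is</sub> + ε, with stepwise AIC selection of the
  informative stages;
- **regional level** — disjoint genomic region classes (promoter, CGI,
  enhancer, exon, intron, intragenic, intergenic; repeats excluded) cut
  into 1-kb tiles (1-Mb windows per chromosome), correlating read-weighted
  methylation with CpG C>T density (CpG C>T SNPs over C/G bases at CpG
  sites) and non-CpG C>T density per tile (Spearman);
- **promoter proxies** — promoter (TSS −1000/+200) CpG observed/expected
  ratio, CpG<sub>O/E</sub> = (N<sub>CpG</sub>·L)/(N<sub>C</sub>·N<sub>G</sub>),
  and promoter CpG SNP density, each correlated with gene expression per
  tissue: expression is a negative proxy for promoter methylation, so
  germline tissues should dominate the extreme ranks.

Because the original inputs are multi-GB population call sets and WGBS
tables, the package ships a first-class **synthetic-data generator**
(`methmut.synthetic_data`) that emulates all five input types — toy genome
with CpG islands, 13 stage methylomes with read-depth noise, a variant
catalog whose per-CpG mutation probability rises with methylation in
designated causal stages, overlapping annotation tracks, and an expression
matrix anti-coupled to promoter methylation in germline tissues — with the
full latent state exposed for recovery testing. Real data in the same
formats (VCF, FASTA, BED, Bismark-CX / bedMethyl tables) run through the
identical code paths.

## Worked example

The numbered drivers under `analysis/` run the default synthetic study
(1 Mb genome, 15× coverage, causal sperm-stage effect β = 0.15) end to end;
each is a thin wrapper over the library:

```sh
cd analysis
python 01_simulate.py --seed 1       # inputs under scratch/analysis/sim
python 02_classify_variants.py
python 03_site_mutability.py
...
python 07_promoter_proxy.py          # tables under results/analysis
```

With seed 1 this prints, among other lines:

```
retained 1,996 rare SNPs; removed per rule: {"symbolic": 12, "indel": 23,
  "multiallelic": 23, "non_autosomal": 0, "frequency_unknown": 0,
  "allele_frequency": 249, "quality": 94}
sperm stage: methylated density 11.22% vs unmethylated 1.13% (chi2 p = 3.61e-07)
sperm bin-trend Pearson r = 0.951
sperm estimate 0.0886 (SE 0.0152, p = 5.61e-09)
stepwise-selected stages: sperm, oocyte, PGC10wf, PGC17wf
tissues ranked by rho(expression, promoter CpG SNP density): 15/20 of the
  lowest 20 are germline
```

Reading: methylated sperm CpGs are ~10× more mutable than unmethylated
ones, the mutation rate rises monotonically across the five methylation
bins, and the regression singles out sperm as the dominant stage. The sperm
coefficient (0.089) is attenuated below the generator's latent effect
(0.15) because 15× read sampling adds noise to the measured levels —
classical errors-in-variables; the deep-coverage recovery study in
`scripts/acceptance.py` recovers β̂ ≈ 0.150. Germline tissues sink to the
bottom of the expression/SNP-density ranking (and, symmetrically, to the
top of the expression/CpG<sub>O/E</sub> ranking, since historical
methylation depresses O/E).

The same stages are exposed as a CLI (`methmut simulate|classify|methylome|
site|patterns|regress|regional|promoter|all -c config.yaml`), driven by a
YAML config whose defaults pin every threshold of the analysis (AF < 0.1%,
QUAL 100, ≥ 5 reads/site, ≥ 5 CpGs/tile, ≥ 10 SNPs/pattern, 1 kb and 1 Mb
windows, 70%/20% state cutoffs).

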