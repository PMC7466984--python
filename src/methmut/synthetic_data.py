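"""Synthetic genomes, methylomes, variant catalogs and expression matrices.

Every pipeline stage is testable without downloads: the generator emits a
toy genome with placed CpGs and CpG islands, 13 stage methylomes with
stage-specific level distributions and read-depth noise, a variant catalog
whose per-CpG mutation probability rises linearly with methylation in
designated causal stages, deliberately overlapping annotation tracks, and
an expression matrix anti-correlated with promoter methylation in germline
tissues. The latent state behind every emitted file is returned as
:class:`SimGroundTruth` for recovery tests.

Model choices
-------------
* Background sequence is i.i.d. over A/C/G/T; CpG depletion outside
  islands is imposed by thinning CG dinucleotides (the C mutates to T with
  the depletion probability), mimicking historical deamination; islands
  are undepleted blocks, so island CpG density exceeds background.
* Latent methylation has exact Beta(a_s, b_s) marginals per stage, coupled
  across stages by a Gaussian copula with one site factor (correlation
  ``stage_correlation``); island CpGs get a negative shift on the site
  factor (hypomethylated CGIs). Reads are Binomial(depth, m(1−ε)+(1−m)ε)
  at Poisson depth; sites below the 5-read floor are emitted anyway so
  that filters are exercised.
* A CpG site mutates with probability b0 + Σ_s β_s·m_{i,s}; a mutated site
  is reported on either cytosine of the dinucleotide with equal chance and
  draws C>T with probability ``ct_share`` (else C>A/C>G equally). Non-CpG
  C/G and T/A bases mutate at a flat rate with fixed type splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from methmut.genomic_io import (
    GenomeSequence,
    Interval,
    write_bed,
    write_fasta,
    write_methylation_table,
)
from methmut.stages import STAGES

#: stage mean methylation defaults: sperm hypermethylated, oocyte and the
#: pre-implantation embryo intermediate after the first demethylation wave,
#: PGCs at the trough of the second wave around weeks 10-13.
DEFAULT_STAGE_MEANS: dict[str, float] = {
    "sperm": 0.85,
    "oocyte": 0.50,
    "8cell": 0.45,
    "morula": 0.40,
    "ICM": 0.45,
    "PGC7wm": 0.35,
    "PGC10wm": 0.25,
    "PGC10wf": 0.25,
    "PGC11wm": 0.15,
    "PGC11wf": 0.15,
    "PGC13wm": 0.20,
    "PGC17wf": 0.25,
    "PGC19wm": 0.30,
}


@dataclass
class GenomeConfig:
    n_chroms: int = 1
    chrom_length: int = 1_000_000
    cpg_rate: float = 0.01          # target background CpG-per-base rate
    base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)  # A C G T
    island_length: int = 2_000      # one undepleted CGI per cassette


@dataclass
class MethylomeConfig:
    stage_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STAGE_MEANS))
    concentration: float = 2.0       # Beta a+b per stage
    stage_correlation: float = 0.6   # copula site-factor share
    domain_length: int = 2_000       # methylation-domain block size (bp)
    domain_share: float = 0.5        # site-factor variance carried by the domain
    island_shift: float = -2.0       # site-factor shift for island CpGs
    depth_mean: float = 15.0         # Poisson read depth
    non_conversion: float = 0.005    # bisulfite error rate epsilon


@dataclass
class MutationConfig:
    baseline: float = 0.01                     # b0
    betas: dict[str, float] = field(default_factory=lambda: {"sperm": 0.15})
    ct_share: float = 0.8                      # P(C>T | CpG mutation)
    noncpg_rate: float = 0.001                 # per eligible non-CpG base


@dataclass
class VariantConfig:
    af_rare_low: float = 5e-5
    af_rare_high: float = 9.9e-4
    common_fraction: float = 0.10   # AF >= 0.1% contamination (exercises the AF filter)
    qual: float = 100.0
    qual_off_fraction: float = 0.05  # records with QUAL != 100
    qual_off_value: float = 60.0
    indel_fraction: float = 0.01
    multiallelic_fraction: float = 0.01
    symbolic_fraction: float = 0.005


@dataclass
class ExpressionConfig:
    n_genes: int | None = None       # None: one row per simulated gene
    germline_coupling: float = -0.5
    somatic_coupling: float = 0.0
    noise_sd: float = 0.1
    # tissue class -> (count, germline flag); 7 classes, 20 germline of 40
    tissue_classes: dict[str, tuple[int, bool]] = field(default_factory=lambda: {
        "primordial_germ": (8, True),
        "male_germ": (6, True),
        "female_germ": (6, True),
        "ESC": (4, False),
        "brain": (6, False),
        "liver": (5, False),
        "GCT": (5, False),
    })


@dataclass
class SimConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    methylome: MethylomeConfig = field(default_factory=MethylomeConfig)
    mutation: MutationConfig = field(default_factory=MutationConfig)
    variants: VariantConfig = field(default_factory=VariantConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def validate(self) -> None:
        g = self.genome
        if g.chrom_length < 1000:
            raise ValueError("chrom_length must be >= 1000")
        if not 0 < g.cpg_rate < 0.5:
            raise ValueError("cpg_rate must lie in (0, 0.5)")
        pA, pC, pG, pT = g.base_composition
        if abs(pA + pC + pG + pT - 1) > 1e-9:
            raise ValueError("base composition must sum to 1")
        if g.cpg_rate > pC * pG:
            raise ValueError(
                f"cpg_rate {g.cpg_rate} exceeds the i.i.d. background rate {pC * pG:.4f}"
            )
        unknown = set(self.mutation.betas) - set(STAGES)
        if unknown:
            raise ValueError(f"betas for unknown stages: {sorted(unknown)}")
        peak = self.mutation.baseline + sum(max(b, 0.0) for b in self.mutation.betas.values())
        if peak > 1:
            raise ValueError(f"baseline + positive betas = {peak} > 1: probability overflow")
        if not self.methylome.depth_mean > 0:
            raise ValueError("depth_mean must be positive")
        missing = [s for s in STAGES if s not in self.methylome.stage_means]
        if missing:
            raise ValueError(f"stage_means missing stages: {missing}")


def recovery_config(seed: int = 0, chrom_length: int = 10_000_000) -> SimConfig:
    """Study conditions for parameter-recovery experiments.

    Deep coverage and a clean catalog (no allele-frequency, quality or
    indel contamination), so that the estimand of the downstream
    regression equals the generator's beta; the default config keeps the
    contamination to exercise every filter instead.
    """
    cfg = SimConfig(seed=seed)
    cfg.genome.chrom_length = chrom_length
    cfg.methylome.depth_mean = 100.0
    cfg.methylome.non_conversion = 0.001
    cfg.variants.common_fraction = 0.0
    cfg.variants.qual_off_fraction = 0.0
    cfg.variants.indel_fraction = 0.0
    cfg.variants.multiallelic_fraction = 0.0
    cfg.variants.symbolic_fraction = 0.0
    return cfg


@dataclass
class SimGroundTruth:
    """Latent state behind the emitted files, for recovery tests."""

    cpg_positions: dict[str, np.ndarray]          # 1-based C positions per chrom
    island_mask: dict[str, np.ndarray]            # per-CpG island membership
    islands: list[Interval]
    latent: dict[str, np.ndarray]                 # (n_cpg, 13) latent levels
    mutated: dict[str, np.ndarray] = field(default_factory=dict)   # per-CpG indicator
    clean: dict[str, np.ndarray] = field(default_factory=dict)     # variant passes default filters
    betas: dict[str, float] = field(default_factory=dict)
    baseline: float = 0.0
    promoter_methylation: pd.Series | None = None  # gene -> true mean latent level

    def to_json(self, path) -> None:
        payload = {
            "betas": self.betas,
            "baseline": self.baseline,
            "chroms": {},
            "promoter_methylation": (
                self.promoter_methylation.round(6).to_dict()
                if self.promoter_methylation is not None else None
            ),
        }
        for chrom in self.cpg_positions:
            payload["chroms"][chrom] = {
                "cpg_positions": self.cpg_positions[chrom].tolist(),
                "island": self.island_mask[chrom].astype(int).tolist(),
                "latent": np.round(self.latent[chrom], 4).tolist(),
                "mutated": self.mutated.get(chrom, np.zeros(0, bool)).astype(int).tolist(),
            }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# genome


#: repeating annotation layout unit; the in-cassette offsets of genes,
#: enhancers and repeats below assume exactly this span
CASSETTE_LENGTH = 100_000


def _island_intervals(cfg: GenomeConfig, chrom: str) -> list[Interval]:
    """One CGI per cassette, at a fixed in-cassette offset (10 kb)."""
    out = []
    for cas in range(0, cfg.chrom_length - CASSETTE_LENGTH + 1, CASSETTE_LENGTH):
        start = cas + 10_000
        out.append(Interval(chrom, start, start + cfg.island_length, name="CGI"))
    return out


def simulate_genome(cfg: SimConfig, rng: np.random.Generator) -> tuple[GenomeSequence, SimGroundTruth]:
    """Generate the toy genome and locate its CpGs.

    i.i.d. background at the configured base composition; outside islands,
    each CG dinucleotide keeps its C with probability
    cpg_rate / (pC·pG) (historical-deamination thinning: the removed Cs
    become T), so the realised background CpG rate matches ``cpg_rate``.
    Deterministic given the generator state.
    """
    cfg.validate()
    g = cfg.genome
    pA, pC, pG, pT = g.base_composition
    keep = g.cpg_rate / (pC * pG)
    sequences: dict[str, str] = {}
    cpg_positions: dict[str, np.ndarray] = {}
    island_mask: dict[str, np.ndarray] = {}
    islands: list[Interval] = []
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for c in range(g.n_chroms):
        chrom = f"chr{c + 1}"
        arr = rng.choice(bases, size=g.chrom_length, p=[pA, pC, pG, pT])
        chrom_islands = _island_intervals(g, chrom)
        islands.extend(chrom_islands)
        in_island = np.zeros(g.chrom_length, dtype=bool)
        for iv in chrom_islands:
            in_island[iv.start : iv.end] = True
        is_cg = np.zeros(g.chrom_length, dtype=bool)
        is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        deplete = is_cg & ~in_island & (rng.random(g.chrom_length) >= keep)
        arr[deplete] = ord("T")
        final_cg = np.zeros(g.chrom_length, dtype=bool)
        final_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        pos0 = np.flatnonzero(final_cg)
        sequences[chrom] = arr.tobytes().decode()
        cpg_positions[chrom] = pos0 + 1  # 1-based C position
        island_mask[chrom] = in_island[pos0]
    genome = GenomeSequence(sequences)
    truth = SimGroundTruth(
        cpg_positions=cpg_positions, island_mask=island_mask, islands=islands, latent={}
    )
    return genome, truth


# ---------------------------------------------------------------------------
# methylomes


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1 - mean) * concentration


def draw_latent(cfg: SimConfig, truth: SimGroundTruth, rng: np.random.Generator) -> None:
    """Draw the latent methylation matrix (n_cpg × 13) per chromosome.

    Exact Beta(a_s, b_s) marginals per stage coupled by a Gaussian copula
    with one shared site factor; the site factor itself mixes a
    methylation-domain block component (``domain_length`` bp, emulating
    the regional smoothness of real methylomes) with an independent
    per-site part. Island CpGs get a negative site-factor shift
    (hypomethylated CGIs). Fills ``truth.latent``.
    """
    m = cfg.methylome
    rho = m.stage_correlation
    for chrom, pos in truth.cpg_positions.items():
        n = len(pos)
        block = (pos - 1) // m.domain_length
        z_block = rng.standard_normal(int(block.max()) + 1 if n else 0)
        z_site = (
            np.sqrt(m.domain_share) * z_block[block]
            + np.sqrt(1 - m.domain_share) * rng.standard_normal(n)
            + np.where(truth.island_mask[chrom], m.island_shift, 0.0)
        )
        latent = np.empty((n, len(STAGES)))
        for j, stage in enumerate(STAGES):
            z = np.sqrt(rho) * z_site + np.sqrt(1 - rho) * rng.standard_normal(n)
            a, b = _beta_params(m.stage_means[stage], m.concentration)
            latent[:, j] = stats.beta.ppf(stats.norm.cdf(z), a, b)
        truth.latent[chrom] = latent


def simulate_methylomes(
    cfg: SimConfig, truth: SimGroundTruth, rng: np.random.Generator
) -> dict[str, pd.DataFrame]:
    """Emit one canonical methylome frame per stage from the latent levels.

    Read depth is Poisson; methylated reads are Binomial at the
    bisulfite-error-adjusted level m(1−ε)+(1−m)ε. Low-depth sites are
    emitted, not suppressed, so downstream filters are exercised. Draws
    the latent matrix first if absent.
    """
    m = cfg.methylome
    if not truth.latent:
        draw_latent(cfg, truth, rng)
    frames: dict[str, list[pd.DataFrame]] = {s: [] for s in STAGES}
    for chrom, pos in truth.cpg_positions.items():
        n = len(pos)
        latent = truth.latent[chrom]
        for j, stage in enumerate(STAGES):
            depth = rng.poisson(m.depth_mean, size=n)
            p_read = latent[:, j] * (1 - m.non_conversion) + (1 - latent[:, j]) * m.non_conversion
            meth = rng.binomial(depth, p_read)
            frames[stage].append(pd.DataFrame({
                "chrom": chrom, "pos": pos, "strand": "+", "context": "CpG",
                "methylated_reads": meth, "total_reads": depth,
            }))
    return {s: pd.concat(parts, ignore_index=True) for s, parts in frames.items()}


# ---------------------------------------------------------------------------
# variants


_CPG_ALT = {  # (strand_is_g, pyrimidine alt) -> (ref, alt)
    (False, "T"): ("C", "T"), (False, "A"): ("C", "A"), (False, "G"): ("C", "G"),
    (True, "T"): ("G", "A"), (True, "A"): ("G", "T"), (True, "G"): ("G", "C"),
}

_NONCPG_ALTS = {
    "C": (("T", 0.5), ("A", 0.25), ("G", 0.25)),
    "G": (("A", 0.5), ("T", 0.25), ("C", 0.25)),   # pyrimidine-strand C>T etc.
    "T": (("C", 1 / 3), ("G", 1 / 3), ("A", 1 / 3)),
    "A": (("G", 1 / 3), ("C", 1 / 3), ("T", 1 / 3)),
}


def simulate_variants(
    cfg: SimConfig, truth: SimGroundTruth, genome: GenomeSequence, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the variant catalog; returns a frame ready for VCF writing.

    Columns: chrom, pos (1-based), ref, alt (comma-joined for injected
    multi-allelics), af, qual, kind (snp/indel/multiallelic/symbolic).
    Updates ``truth.mutated`` and ``truth.clean`` per CpG site.
    """
    mu = cfg.mutation
    v = cfg.variants
    rows: list[pd.DataFrame] = []
    for chrom, pos in truth.cpg_positions.items():
        latent = truth.latent[chrom]
        p = np.full(len(pos), mu.baseline)
        for stage, beta in mu.betas.items():
            p = p + beta * latent[:, STAGES.index(stage)]
        p = np.clip(p, 0.0, 1.0)
        mutated = rng.random(len(pos)) < p
        truth.mutated[chrom] = mutated
        idx = np.flatnonzero(mutated)
        on_g = rng.random(len(idx)) < 0.5
        u = rng.random(len(idx))
        pyr_alt = np.where(u < mu.ct_share, "T", np.where(u < mu.ct_share + (1 - mu.ct_share) / 2, "A", "G"))
        refs = np.empty(len(idx), dtype=object)
        alts = np.empty(len(idx), dtype=object)
        for k in range(len(idx)):
            refs[k], alts[k] = _CPG_ALT[(bool(on_g[k]), str(pyr_alt[k]))]
        cpg_var = pd.DataFrame({
            "chrom": chrom,
            "pos": pos[idx] + on_g.astype(np.int64),
            "ref": refs, "alt": alts, "kind": "snp",
        })

        # non-CpG background mutations at a flat rate
        arr = genome.byte_array(chrom)
        cpg_base = np.zeros(len(arr), dtype=bool)
        cpg_base[pos - 1] = True
        cpg_base[pos] = True  # G of the dinucleotide (pos is 1-based C)
        eligible = ~cpg_base & np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
        hit = eligible & (rng.random(len(arr)) < mu.noncpg_rate)
        hit_pos0 = np.flatnonzero(hit)
        nrefs = np.array([chr(b) for b in arr[hit_pos0]], dtype=object)
        nalts = np.empty(len(hit_pos0), dtype=object)
        uu = rng.random(len(hit_pos0))
        for base, choices in _NONCPG_ALTS.items():
            mask = nrefs == base
            edges = np.cumsum([w for _, w in choices])
            pick = np.searchsorted(edges, uu[mask], side="right")
            pick = np.minimum(pick, len(choices) - 1)
            nalts[mask] = np.array([a for a, _ in choices], dtype=object)[pick]
        noncpg_var = pd.DataFrame({
            "chrom": chrom, "pos": hit_pos0 + 1, "ref": nrefs, "alt": nalts, "kind": "snp",
        })
        rows.append(pd.concat([cpg_var, noncpg_var], ignore_index=True))

    snps = pd.concat(rows, ignore_index=True)

    n = len(snps)
    common = rng.random(n) < v.common_fraction
    af = np.where(
        common,
        rng.uniform(1e-3, 5e-2, size=n),
        rng.uniform(v.af_rare_low, v.af_rare_high, size=n),
    )
    qual_off = rng.random(n) < v.qual_off_fraction
    qual = np.where(qual_off, v.qual_off_value, v.qual)
    snps["af"] = af
    snps["qual"] = qual

    # record, per CpG site, whether its variant survives the default filters
    for chrom in truth.cpg_positions:
        mutated = truth.mutated[chrom]
        clean = np.zeros(len(mutated), dtype=bool)
        sub = snps[(snps["chrom"] == chrom) & (snps["kind"] == "snp")]
        ok = sub[(sub["af"] < 1e-3) & (sub["qual"] == 100.0)]
        site_pos = np.where(
            np.isin(ok["ref"].to_numpy(), ("G",)), ok["pos"].to_numpy() - 1, ok["pos"].to_numpy()
        )
        clean_sites = np.isin(truth.cpg_positions[chrom], site_pos)
        clean = mutated & clean_sites
        truth.clean[chrom] = clean

    # contamination records exercising the structural filters
    extra_rows = []
    first_chrom = next(iter(truth.cpg_positions))
    arr = genome.byte_array(first_chrom)
    free = np.flatnonzero(np.isin(arr, np.frombuffer(b"AT", dtype=np.uint8)))
    n_indel = int(round(v.indel_fraction * n))
    n_multi = int(round(v.multiallelic_fraction * n))
    n_sym = int(round(v.symbolic_fraction * n))
    need = n_indel + n_multi + n_sym
    if need:
        chosen = rng.choice(free, size=need, replace=False)
        kinds = ["indel"] * n_indel + ["multiallelic"] * n_multi + ["symbolic"] * n_sym
        for pos0, kind in zip(chosen, kinds):
            ref = chr(arr[pos0])
            if kind == "indel":
                alt = ref + "T"
            elif kind == "multiallelic":
                alt = "C,G"
            else:
                alt = "<DEL>"
            extra_rows.append((first_chrom, int(pos0) + 1, ref, alt, kind,
                               float(rng.uniform(v.af_rare_low, v.af_rare_high)), v.qual))
    if extra_rows:
        extra = pd.DataFrame(extra_rows, columns=["chrom", "pos", "ref", "alt", "kind", "af", "qual"])
        snps = pd.concat([snps, extra], ignore_index=True)

    snps = snps.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    truth.betas = dict(mu.betas)
    truth.baseline = mu.baseline
    return snps


def write_vcf(path, variants: pd.DataFrame, genome: GenomeSequence) -> None:
    """Write the simulated catalog as a minimal VCF 4.2 with INFO/AF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=methmut-simulate\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        for chrom, length in genome.lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in variants.itertuples(index=False):
            n_alts = row.alt.count(",") + 1
            af = ",".join([f"{row.af:.6g}"] * n_alts)
            qual = f"{row.qual:g}"
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t{qual}\tPASS\tAF={af}\n")


#: expected filter-report outcome of :func:`toy_filter_vcf`
TOY_VCF_EXPECTED = {
    "retained": 6,
    "removed": {
        "symbolic": 2, "indel": 2, "multiallelic": 2, "non_autosomal": 2,
        "frequency_unknown": 1, "allele_frequency": 3, "quality": 2,
    },
}


def toy_filter_vcf(path) -> dict:
    """Write a 20-record VCF exercising every removal rule once or more.

    Six records pass all filters (rare autosomal biallelic SNPs at QUAL
    100); the rest hit, in rule order: 2 symbolic alts, 2 indels, 2
    multi-allelics, 2 chrX records, 1 record with no resolvable allele
    frequency, 3 records at AF >= 0.1%, 2 records at QUAL != 100. Returns
    :data:`TOY_VCF_EXPECTED`.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=INS,Description="Insertion">',
        "##contig=<ID=chr1,length=100000>",
        "##contig=<ID=chrX,length=100000>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        # retained
        "chr1\t100\t.\tA\tG\t100\tPASS\tAF=0.0005",
        "chr1\t200\t.\tC\tT\t100\tPASS\tAF=0.0002",
        "chr1\t300\t.\tG\tA\t100\tPASS\tAF=0.0009",
        "chr1\t400\t.\tT\tC\t100\tPASS\tAF=0.0001",
        "chr1\t500\t.\tC\tA\t100\tPASS\tAF=0.0004",
        "chr1\t600\t.\tG\tC\t100\tPASS\tAF=0.0003",
        # symbolic / structural
        "chr1\t700\t.\tA\t<DEL>\t100\tPASS\tAF=0.0005",
        "chr1\t800\t.\tC\t<INS>\t100\tPASS\tAF=0.0005",
        # indels
        "chr1\t900\t.\tA\tAT\t100\tPASS\tAF=0.0005",
        "chr1\t1000\t.\tCT\tC\t100\tPASS\tAF=0.0005",
        # multi-allelic
        "chr1\t1100\t.\tA\tC,G\t100\tPASS\tAF=0.0002,0.0003",
        "chr1\t1200\t.\tG\tA,T\t100\tPASS\tAF=0.0001,0.0001",
        # non-autosomal
        "chrX\t1300\t.\tA\tG\t100\tPASS\tAF=0.0005",
        "chrX\t1400\t.\tC\tT\t100\tPASS\tAF=0.0005",
        # no resolvable allele frequency
        "chr1\t1500\t.\tA\tG\t100\tPASS\t.",
        # allele frequency >= 0.1%
        "chr1\t1600\t.\tA\tG\t100\tPASS\tAF=0.002",
        "chr1\t1700\t.\tC\tT\t100\tPASS\tAF=0.01",
        "chr1\t1800\t.\tG\tA\t100\tPASS\tAF=0.5",
        # quality != 100
        "chr1\t1900\t.\tA\tG\t90\tPASS\tAF=0.0005",
        "chr1\t2000\t.\tC\tT\t50\tPASS\tAF=0.0005",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
    return {"retained": TOY_VCF_EXPECTED["retained"],
            "removed": dict(TOY_VCF_EXPECTED["removed"])}


# ---------------------------------------------------------------------------
# annotations


def simulate_annotations(cfg: SimConfig, truth: SimGroundTruth) -> dict[str, list[Interval]]:
    """Deterministic annotation tracks on a repeating 100-kb cassette.

    Each cassette carries six genes (three per strand): one CGI-promoter
    gene on the plus strand whose promoter overlaps both the island and an
    enhancer (so the promoter-enhancer and CGI-enhancer eliminations are
    exercised), plus three with plain promoters; a standalone and an
    intragenic enhancer; and repeats inside a gene and in intergenic
    space.
    """
    g = cfg.genome
    genes: list[Interval] = []
    exons: list[Interval] = []
    enhancers: list[Interval] = []
    repeats: list[Interval] = []
    chroms = sorted({iv.chrom for iv in truth.islands}, key=lambda c: int(c.replace("chr", "")))
    for chrom in chroms:
        k = 0
        for cas in range(0, g.chrom_length - CASSETTE_LENGTH + 1, CASSETTE_LENGTH):
            k += 1
            a_name, b_name = f"{chrom}_gA{k}", f"{chrom}_gB{k}"
            # plus-strand gene, TSS just inside the island -> CGI promoter
            genes.append(Interval(chrom, cas + 11_800, cas + 21_800, "+", a_name))
            exons += [
                Interval(chrom, cas + 11_800, cas + 12_800, "+", a_name),
                Interval(chrom, cas + 16_000, cas + 17_000, "+", a_name),
                Interval(chrom, cas + 20_800, cas + 21_800, "+", a_name),
            ]
            # minus-strand gene, TSS at its right end, plain promoter
            genes.append(Interval(chrom, cas + 40_000, cas + 50_000, "-", b_name))
            exons += [
                Interval(chrom, cas + 40_000, cas + 41_000, "-", b_name),
                Interval(chrom, cas + 44_000, cas + 45_000, "-", b_name),
                Interval(chrom, cas + 49_000, cas + 50_000, "-", b_name),
            ]
            c_name, d_name = f"{chrom}_gC{k}", f"{chrom}_gD{k}"
            genes.append(Interval(chrom, cas + 70_000, cas + 78_000, "+", c_name))
            exons += [
                Interval(chrom, cas + 70_000, cas + 71_000, "+", c_name),
                Interval(chrom, cas + 73_500, cas + 74_500, "+", c_name),
                Interval(chrom, cas + 77_000, cas + 78_000, "+", c_name),
            ]
            genes.append(Interval(chrom, cas + 82_000, cas + 90_000, "-", d_name))
            exons += [
                Interval(chrom, cas + 82_000, cas + 83_000, "-", d_name),
                Interval(chrom, cas + 85_500, cas + 86_500, "-", d_name),
                Interval(chrom, cas + 89_000, cas + 90_000, "-", d_name),
            ]
            e_name, f_name = f"{chrom}_gE{k}", f"{chrom}_gF{k}"
            genes.append(Interval(chrom, cas + 52_000, cas + 58_000, "+", e_name))
            exons += [
                Interval(chrom, cas + 52_000, cas + 53_000, "+", e_name),
                Interval(chrom, cas + 54_500, cas + 55_500, "+", e_name),
                Interval(chrom, cas + 57_000, cas + 58_000, "+", e_name),
            ]
            genes.append(Interval(chrom, cas + 91_000, cas + 97_000, "-", f_name))
            exons += [
                Interval(chrom, cas + 91_000, cas + 92_000, "-", f_name),
                Interval(chrom, cas + 93_500, cas + 94_500, "-", f_name),
                Interval(chrom, cas + 96_000, cas + 97_000, "-", f_name),
            ]
            enhancers += [
                Interval(chrom, cas + 10_500, cas + 11_500, ".", "enh_po"),   # in island+promoter
                Interval(chrom, cas + 44_500, cas + 45_500, ".", "enh_gene"),
                Interval(chrom, cas + 60_000, cas + 61_000, ".", "enh_free"),
                Interval(chrom, cas + 63_000, cas + 64_000, ".", "enh_free"),
                Interval(chrom, cas + 78_500, cas + 79_500, ".", "enh_free"),
            ]
            repeats += [
                Interval(chrom, cas + 18_000, cas + 18_400, ".", "rep_gene"),
                Interval(chrom, cas + 30_000, cas + 30_400, ".", "rep_free"),
                Interval(chrom, cas + 65_000, cas + 65_400, ".", "rep_free"),
            ]
    return {
        "genes": genes,
        "exons": exons,
        "cgis": list(truth.islands),
        "enhancers": enhancers,
        "repeats": repeats,
    }


def true_promoter_methylation(cfg: SimConfig, truth: SimGroundTruth, genes: list[Interval]) -> pd.Series:
    """Mean latent level (over stages and promoter CpGs) per gene."""
    from methmut.regional_association import promoter_intervals

    chrom_lengths = {c: cfg.genome.chrom_length for c in truth.cpg_positions}
    values = {}
    for g in genes:
        prom = promoter_intervals([g], chrom_lengths)
        if prom.empty:
            continue
        chrom = g.chrom
        start, end = int(prom.iloc[0]["Start"]), int(prom.iloc[0]["End"])
        pos = truth.cpg_positions[chrom]
        in_prom = (pos >= start + 1) & (pos <= end)
        if in_prom.sum() == 0:
            continue
        values[g.name] = float(truth.latent[chrom][in_prom].mean())
    series = pd.Series(values, name="promoter_methylation")
    truth.promoter_methylation = series
    return series


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    cfg: SimConfig,
    promoter_methylation: pd.Series | None,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix (genes × tissues) plus tissue class labels.

    expression[g, t] = c_t · methylation(g) + Normal(0, noise_sd), with
    c_t = ``germline_coupling`` for germline tissues and
    ``somatic_coupling`` otherwise. Without a promoter-methylation vector
    (standalone mode), per-gene methylation is drawn Beta(2, 2) at
    ``n_genes`` genes.
    """
    e = cfg.expression
    if promoter_methylation is None:
        if e.n_genes is None:
            raise ValueError("n_genes required in standalone expression mode")
        meth = pd.Series(rng.beta(2, 2, size=e.n_genes),
                         index=[f"gene{i + 1}" for i in range(e.n_genes)])
    else:
        meth = promoter_methylation
    tissues, classes, germline = [], [], []
    for cls, (count, is_germ) in e.tissue_classes.items():
        for i in range(count):
            tissues.append(f"{cls}_{i + 1}")
            classes.append(cls)
            germline.append(is_germ)
    coupling = np.where(germline, e.germline_coupling, e.somatic_coupling)
    noise = rng.normal(0.0, e.noise_sd, size=(len(meth), len(tissues)))
    matrix = meth.to_numpy()[:, None] * coupling[None, :] + noise
    expr = pd.DataFrame(matrix, index=meth.index, columns=tissues)
    expr.index.name = "gene"
    tissue_df = pd.DataFrame({"tissue": tissues, "tissue_class": classes, "germline": germline})
    return expr, tissue_df


# ---------------------------------------------------------------------------
# one-call simulation and file emission


def simulate_all(cfg: SimConfig):
    """Run the full generator in memory.

    Returns ``(genome, truth, methylomes, variants, tracks, expression,
    tissue_classes)``; all randomness flows from ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genome, truth = simulate_genome(cfg, rng)
    methylomes = simulate_methylomes(cfg, truth, rng)
    variants = simulate_variants(cfg, truth, genome, rng)
    tracks = simulate_annotations(cfg, truth)
    prom_meth = true_promoter_methylation(cfg, truth, tracks["genes"])
    expr, tissue_df = simulate_expression(cfg, prom_meth, rng)
    return genome, truth, methylomes, variants, tracks, expr, tissue_df


def write_outputs(outdir, cfg: SimConfig, genome, truth, methylomes, variants,
                  tracks, expr, tissue_df) -> dict[str, str]:
    """Emit FASTA, VCF, 13 methylation TSVs, BED tracks, expression tables
    and the ground-truth JSON under *outdir*; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    write_fasta(outdir / "genome.fa", genome)
    paths["genome"] = str(outdir / "genome.fa")
    write_vcf(outdir / "variants.vcf", variants, genome)
    paths["vcf"] = str(outdir / "variants.vcf")
    for stage, df in methylomes.items():
        p = outdir / f"methylome_{stage}.tsv"
        write_methylation_table(p, df, provenance=f"stage={stage} seed={cfg.seed}")
        paths[f"methylome_{stage}"] = str(p)
    for track, ivs in tracks.items():
        p = outdir / f"{track}.bed"
        write_bed(p, ivs, provenance=f"track={track} seed={cfg.seed}")
        paths[track] = str(p)
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    paths["expression"] = str(outdir / "expression.tsv")
    tissue_df.to_csv(outdir / "tissue_classes.tsv", sep="\t", index=False)
    paths["tissue_classes"] = str(outdir / "tissue_classes.tsv")
    truth.to_json(outdir / "ground_truth.json")
    paths["ground_truth"] = str(outdir / "ground_truth.json")
    return paths
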