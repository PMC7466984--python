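"""End-to-end orchestration: configuration, stage wiring, manifests.

Each ``run_*`` function reads its inputs through :mod:`methmut.genomic_io`,
executes one analysis stage and writes TSV/JSON outputs; :func:`run_all`
chains them. All thresholds live in :class:`PipelineConfig` with defaults
equal to the study's stated cutoffs (AF < 0.1%, QUAL 100, >= 5 reads,
>= 5 CpGs per tile, >= 10 SNPs per pattern, 1 kb / 1 Mb windows,
H/M/U at 70%/20%). Reruns with identical inputs are byte-identical; a
run manifest records the config hash and input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import methmut
from methmut import genomic_io, methylome, mutability, promoter_proxy, regional_association
from methmut import stage_regression, variant_catalog
from methmut.stages import STAGES

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    outdir: str = "results"
    fasta: str = ""
    vcf: str = ""
    methylomes: dict[str, str] = field(default_factory=dict)  # stage -> path
    methylation_dialect: str = "canonical"
    genes_bed: str = ""
    exons_bed: str = ""
    cgis_bed: str = ""
    enhancers_bed: str = ""
    repeats_bed: str = ""
    expression_tsv: str = ""
    tissue_classes_tsv: str = ""
    autosomes: list[str] = field(default_factory=list)  # empty: all FASTA chroms

    af_max: float = 0.001
    min_qual: float = 100.0
    min_reads: int = 5
    binom_p0: float = 0.01
    binom_alpha: float = 0.05
    merge_strands: bool = False
    min_cpg_per_tile: int = 5
    min_snps_per_pattern: int = 10
    top_k_patterns: int = 20
    regional_window: int = 1_000
    chromosomal_window: int = 1_000_000
    drop_partial_tiles: bool = False
    stepwise_direction: str = "both"
    min_shared_genes: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_manifest(cfg: PipelineConfig, outdir: Path, inputs: list[str], outputs: list[str]) -> None:
    manifest = {
        "version": methmut.__version__,
        "config_hash": cfg.config_hash(),
        "config": yaml.safe_load(cfg.to_yaml()),
        "inputs": {p: _checksum(p) for p in inputs if p and Path(p).exists()},
        "outputs": sorted(Path(o).name for o in outputs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# loading helpers


def load_genome(cfg: PipelineConfig) -> genomic_io.GenomeSequence:
    _require(cfg.fasta, "fasta")
    return genomic_io.read_fasta(cfg.fasta)


def load_methylomes(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    frames = {}
    for stage in STAGES:
        path = cfg.methylomes.get(stage, "")
        _require(path, f"methylomes.{stage}")
        frames[stage] = genomic_io.read_methylation_table(
            path, stage_id=stage, dialect=cfg.methylation_dialect
        )
    return frames


def load_catalog(outdir: Path) -> pd.DataFrame:
    path = outdir / "catalog.tsv"
    _require(str(path), "catalog (run `classify` first)")
    return pd.read_csv(path, sep="\t")


def _require(path: str, what: str) -> None:
    if not path or not Path(path).exists():
        raise FileNotFoundError(f"missing input: {what} ({path or 'unset'})")


def _tracks(cfg: PipelineConfig):
    for key in ("genes_bed", "exons_bed", "cgis_bed", "enhancers_bed", "repeats_bed"):
        _require(getattr(cfg, key), key)
    return (
        genomic_io.read_bed(cfg.genes_bed),
        genomic_io.read_bed(cfg.exons_bed),
        genomic_io.read_bed(cfg.cgis_bed),
        genomic_io.read_bed(cfg.enhancers_bed),
        genomic_io.read_bed(cfg.repeats_bed),
    )


# ---------------------------------------------------------------------------
# stages


def run_classify(cfg: PipelineConfig) -> dict:
    """Filter the VCF to the rare-SNP set and classify mutation types."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = load_genome(cfg)
    _require(cfg.vcf, "vcf")
    autosomes = cfg.autosomes or list(genome.sequences)
    catalog, report = variant_catalog.filter_variants(
        genomic_io.read_vcf(cfg.vcf), autosomes, af_max=cfg.af_max, qual=cfg.min_qual
    )
    catalog, n_unclassified = variant_catalog.classify_catalog(catalog, genome)
    props, _ = variant_catalog.type_proportions(catalog)
    _write_tsv(outdir / "catalog.tsv", catalog)
    payload = report.to_dict()
    payload["unclassified"] = n_unclassified
    payload["type_proportions"] = {k: round(v, 6) for k, v in sorted(props.items())}
    (outdir / "filter_report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    write_manifest(cfg, outdir, [cfg.fasta, cfg.vcf], ["catalog.tsv", "filter_report.json"])
    return payload


def run_methylome(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Depth-filter, level, call, bin and 3-state every stage methylome."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = load_methylomes(cfg)
    annotated = {}
    for stage, df in frames.items():
        ann = methylome.annotate_stage(
            df, p0=cfg.binom_p0, alpha=cfg.binom_alpha,
            min_reads=cfg.min_reads, merge_strands=cfg.merge_strands,
        )
        annotated[stage] = ann
        _write_tsv(outdir / f"sites_{stage}.tsv",
                   ann[["chrom", "pos", "level", "call", "bin", "three_state"]])
    common = methylome.common_sites(frames, min_reads=cfg.min_reads)
    _write_tsv(outdir / "common_sites.tsv", common)
    return annotated


def run_site(cfg: PipelineConfig) -> pd.DataFrame:
    """Site-level mutability per stage and methylation category, with the
    bin-trend Pearson r and the 2x2 chi-squared test."""
    outdir = Path(cfg.outdir)
    annotated = run_methylome(cfg)
    catalog = load_catalog(outdir)
    rows = []
    for stage in STAGES:
        profile = mutability.stage_bin_profile(annotated[stage], catalog, stage)
        tab = profile.table.assign(stage=stage)
        try:
            r, p = mutability.bin_trend_correlation(profile)
        except ValueError:
            r, p = np.nan, np.nan
        try:
            chi2, chi2_p = mutability.meth_vs_unmeth_test(profile)
        except ValueError:
            chi2, chi2_p = np.nan, np.nan
        tab["bin_trend_r"] = r
        tab["bin_trend_p"] = p
        tab["meth_vs_unmeth_chi2"] = chi2
        tab["meth_vs_unmeth_p"] = chi2_p
        rows.append(tab)
    table = pd.concat(rows, ignore_index=True)
    table = table[["stage", "category", "n_sites", "n_snps", "density",
                   "bin_trend_r", "bin_trend_p", "meth_vs_unmeth_chi2", "meth_vs_unmeth_p"]]
    _write_tsv(outdir / "site_mutability.tsv", table)
    return table


def run_patterns(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Dynamic methylation patterns with SNP densities and the top-k table."""
    outdir = Path(cfg.outdir)
    frames = load_methylomes(cfg)
    catalog = load_catalog(outdir)
    common = methylome.common_sites(frames, min_reads=cfg.min_reads)
    patterned, n_unique = mutability.enumerate_patterns(common)
    full, top = mutability.pattern_mutability(
        patterned, catalog, min_snps=cfg.min_snps_per_pattern, top_k=cfg.top_k_patterns
    )
    _write_tsv(outdir / "pattern_mutability.tsv", full)
    _write_tsv(outdir / "pattern_top.tsv", top)
    (outdir / "pattern_summary.json").write_text(
        json.dumps({"n_unique_patterns": n_unique, "n_common_sites": len(patterned)})
    )
    return full, top, n_unique


def run_regress(cfg: PipelineConfig) -> pd.DataFrame:
    """Per-site OLS of mutation state on the 13 stage levels + stepwise AIC."""
    outdir = Path(cfg.outdir)
    frames = load_methylomes(cfg)
    catalog = load_catalog(outdir)
    common = methylome.common_sites(frames, min_reads=cfg.min_reads)
    design = stage_regression.build_design(common, catalog)
    full = stage_regression.fit_ols(design)
    step = stage_regression.stepwise_select(design, direction=cfg.stepwise_direction)
    table = stage_regression.regression_table(full, step)
    _write_tsv(outdir / "stage_regression.tsv", table)
    return table


def run_regional(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region-class and chromosome tile correlation tables."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = load_genome(cfg)
    frames = load_methylomes(cfg)
    catalog = load_catalog(outdir)
    genes, exons, cgis, enhancers, repeats = _tracks(cfg)
    classes = regional_association.build_region_annotation(
        genes, exons, cgis, enhancers, repeats, genome.lengths
    )
    tile_frames = []
    for name, intervals in classes.items():
        if intervals.empty:
            continue
        tiles = regional_association.tile_regions(
            intervals, window=cfg.regional_window, drop_partial=cfg.drop_partial_tiles
        )
        if tiles.empty:
            continue
        stats_df = regional_association.tile_stats(
            tiles, genome, frames, catalog, min_cpg=cfg.min_cpg_per_tile
        )
        stats_df.insert(0, "region_class", name)
        tile_frames.append(stats_df)
    regional_tiles = pd.concat(tile_frames, ignore_index=True)
    _write_tsv(outdir / "regional_tiles.tsv", regional_tiles)
    regional_corr = regional_association.region_correlations(regional_tiles, group_col="region_class")
    _write_tsv(outdir / "regional_correlations.tsv", regional_corr)

    chrom_tiles = regional_association.tile_chromosomes(
        genome.lengths, window=cfg.chromosomal_window
    )
    chrom_stats = regional_association.tile_stats(
        chrom_tiles, genome, frames, catalog, min_cpg=cfg.min_cpg_per_tile
    )
    chrom_stats.insert(0, "chromosome", chrom_stats["Chromosome"])
    chrom_corr = regional_association.region_correlations(
        chrom_stats, group_col="chromosome", min_tiles=3
    )
    _write_tsv(outdir / "chromosome_correlations.tsv", chrom_corr)
    return regional_corr, chrom_corr


def run_promoter(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promoter CpG O/E + SNP density vs expression across tissues."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = load_genome(cfg)
    catalog = load_catalog(outdir)
    genes = [g for g in genomic_io.read_bed(cfg.genes_bed)]
    stats_df = promoter_proxy.promoter_stats(genes, genome, catalog)
    _write_tsv(outdir / "promoter_stats.tsv", stats_df)
    _require(cfg.expression_tsv, "expression_tsv")
    _require(cfg.tissue_classes_tsv, "tissue_classes_tsv")
    expr = pd.read_csv(cfg.expression_tsv, sep="\t", index_col=0)
    tissue_classes = pd.read_csv(cfg.tissue_classes_tsv, sep="\t")
    out = {}
    for stat in ("cpg_snp_density", "cpg_oe"):
        series = stats_df.set_index("gene")[stat]
        table, n_bottom = promoter_proxy.expression_correlations(
            expr, series, tissue_classes, min_shared_genes=cfg.min_shared_genes
        )
        table["statistic"] = stat
        _write_tsv(outdir / f"expression_vs_{stat}.tsv", table)
        out[stat] = (table, n_bottom)
    return out["cpg_snp_density"], out["cpg_oe"]


def run_all(cfg: PipelineConfig) -> dict:
    """Chain every stage; returns a summary dict of headline quantities."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    classify = run_classify(cfg)
    site = run_site(cfg)
    _, top, n_unique = run_patterns(cfg)
    regress = run_regress(cfg)
    regional_corr, chrom_corr = run_regional(cfg)
    density_table, oe_table = run_promoter(cfg)
    summary = {
        "n_snps_retained": classify["retained"],
        "n_unique_patterns": n_unique,
        "sperm_meth_density": float(
            site.query("stage=='sperm' and category=='methylated'")["density"].iloc[0]
        ),
        "sperm_unmeth_density": float(
            site.query("stage=='sperm' and category=='unmethylated'")["density"].iloc[0]
        ),
        "beta_sperm": float(regress.set_index("term").loc["sperm", "estimate"]),
        "germline_in_bottom20_density": int(density_table[0].head(20)["germline"].sum()),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    inputs = [cfg.fasta, cfg.vcf, *cfg.methylomes.values(), cfg.genes_bed, cfg.exons_bed,
              cfg.cgis_bed, cfg.enhancers_bed, cfg.repeats_bed, cfg.expression_tsv,
              cfg.tissue_classes_tsv]
    outputs = [str(p) for p in outdir.glob("*.tsv")] + [str(outdir / "summary.json")]
    write_manifest(cfg, outdir, inputs, outputs)
    return summary
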