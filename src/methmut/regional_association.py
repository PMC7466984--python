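"""Genomic-region classes, tiling, and regional methylation-mutability links.

The genome is partitioned into disjoint region classes (promoter, CGI,
enhancer, intragenic/exon/intron, intergenic, repeat), each class is cut
into fixed-width tiles (1 kb regional, 1 Mb chromosomal), and per tile two
mutation-rate measures are computed — CpG C>T density (CpG C>T SNPs over
C/G bases at CpG sites) and non-CpG C>T density (same over non-CpG C/G
bases) — alongside the read-weighted methylation level per stage. The
deliverable is the Spearman correlation of methylation against each
measure per region class (or chromosome) and stage.

Disjointification precedence (documented, since overlapping raw tracks
must yield disjoint classes): repeats are excluded from every other class
(last); enhancers lose their overlap with promoters and CGIs; CGIs lose
their overlap with promoters; gene-body classes (intragenic = exon ∪
intron) lose their overlap with promoter/CGI/enhancer; intergenic is the
complement of everything annotated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats

from methmut.genomic_io import GenomeSequence
from methmut.stages import STAGES
from methmut.variant_catalog import MutationType

REGION_CLASSES = (
    "promoter", "CGI", "enhancer", "intergenic", "intragenic", "exon", "intron", "repeat",
)

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 200

REGIONAL_WINDOW = 1_000
CHROMOSOMAL_WINDOW = 1_000_000
MIN_CPG_PER_TILE = 5
MIN_TILES_PER_GROUP = 10


# ---------------------------------------------------------------------------
# interval algebra (thin wrappers over pyranges; always merge first)


def _frame(intervals) -> pd.DataFrame:
    if isinstance(intervals, pd.DataFrame):
        return intervals[["Chromosome", "Start", "End"]].copy()
    return pd.DataFrame(
        {
            "Chromosome": [iv.chrom for iv in intervals],
            "Start": [iv.start for iv in intervals],
            "End": [iv.end for iv in intervals],
        }
    )


def merge_intervals(intervals) -> pd.DataFrame:
    df = _frame(intervals)
    if df.empty:
        return df
    out = pr.PyRanges(df).merge().df
    return out.sort_values(["Chromosome", "Start"]).reset_index(drop=True)


def subtract_intervals(left, right) -> pd.DataFrame:
    ldf, rdf = merge_intervals(left), merge_intervals(right)
    if ldf.empty or rdf.empty:
        return ldf
    out = pr.PyRanges(ldf).subtract(pr.PyRanges(rdf)).df
    if out.empty:
        return out
    return out[["Chromosome", "Start", "End"]].sort_values(["Chromosome", "Start"]).reset_index(drop=True)


def union_intervals(*interval_sets) -> pd.DataFrame:
    frames = [_frame(s) for s in interval_sets]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(columns=["Chromosome", "Start", "End"])
    return merge_intervals(pd.concat(frames, ignore_index=True))


def complement_intervals(intervals, chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Genome minus the given intervals, per chromosome."""
    merged = merge_intervals(intervals)
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = merged[merged["Chromosome"] == chrom]
        prev = 0
        for _, r in sub.iterrows():
            if r["Start"] > prev:
                rows.append((chrom, prev, r["Start"]))
            prev = max(prev, r["End"])
        if prev < length:
            rows.append((chrom, prev, length))
    return pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])


def intersection_size(a, b) -> int:
    """Total overlapping bases between two interval sets (disjointness checks)."""
    adf, bdf = merge_intervals(a), merge_intervals(b)
    if adf.empty or bdf.empty:
        return 0
    inter = pr.PyRanges(adf).intersect(pr.PyRanges(bdf)).df
    if inter.empty:
        return 0
    return int((inter["End"] - inter["Start"]).sum())


# ---------------------------------------------------------------------------
# region classes


def promoter_intervals(genes, chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Strand-aware promoters: −1000/+200 around the TSS, clipped to bounds."""
    rows = []
    for g in genes:
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.name or g} lacks a strand; promoters need TSS orientation")
        if g.strand == "+":
            tss = g.start
            start, end = tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
        else:
            tss = g.end - 1
            start, end = tss - PROMOTER_DOWNSTREAM + 1, tss + PROMOTER_UPSTREAM + 1
        length = chrom_lengths[g.chrom]
        start, end = max(0, start), min(length, end)
        if end > start:
            rows.append((g.chrom, start, end))
    return merge_intervals(pd.DataFrame(rows, columns=["Chromosome", "Start", "End"]))


def build_region_annotation(
    genes, exons, cgis, enhancers, repeats, chrom_lengths: dict[str, int]
) -> dict[str, pd.DataFrame]:
    """Build the disjoint region classes from raw annotation tracks.

    *genes* must carry strands (for promoters); all arguments are interval
    collections (:class:`Interval` lists or pyranges-style frames). Returns
    a map class name -> merged, sorted interval frame.
    """
    promoter = promoter_intervals(genes, chrom_lengths)
    gene_body = merge_intervals(genes)
    exon = merge_intervals(exons)
    cgi = merge_intervals(cgis)
    enhancer = merge_intervals(enhancers)
    repeat = merge_intervals(repeats)

    higher = union_intervals(promoter, cgi, enhancer)
    cgi_d = subtract_intervals(cgi, promoter)
    enhancer_d = subtract_intervals(enhancer, union_intervals(promoter, cgi))
    exon_in = subtract_intervals(pr.PyRanges(exon).intersect(pr.PyRanges(gene_body)).df
                                 if not exon.empty and not gene_body.empty else exon, higher)
    intron = subtract_intervals(subtract_intervals(gene_body, exon), higher)
    intragenic = subtract_intervals(gene_body, higher)
    annotated = union_intervals(gene_body, promoter, cgi, enhancer, repeat)
    intergenic = complement_intervals(annotated, chrom_lengths)

    classes = {
        "promoter": promoter,
        "CGI": cgi_d,
        "enhancer": enhancer_d,
        "intergenic": intergenic,
        "intragenic": intragenic,
        "exon": exon_in,
        "intron": intron,
    }
    # repeats excluded from every other class, last
    classes = {name: subtract_intervals(df, repeat) for name, df in classes.items()}
    classes["repeat"] = repeat
    return classes


# ---------------------------------------------------------------------------
# tiling and per-tile statistics


def tile_regions(intervals, window: int = REGIONAL_WINDOW, drop_partial: bool = False) -> pd.DataFrame:
    """Cut merged intervals into consecutive windows from each start.

    Terminal partial windows are retained by default (they still face the
    >= 5 CpG filter downstream); ``drop_partial`` discards them.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    df = _frame(intervals)
    rows = []
    for chrom, start, end in df[["Chromosome", "Start", "End"]].itertuples(index=False):
        edges = np.arange(start, end, window)
        for s in edges:
            e = min(s + window, end)
            if drop_partial and e - s < window:
                continue
            rows.append((chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])


def tile_chromosomes(chrom_lengths: dict[str, int], window: int = CHROMOSOMAL_WINDOW) -> pd.DataFrame:
    frames = [
        pd.DataFrame({"Chromosome": chrom, "Start": 0, "End": length}, index=[0])
        for chrom, length in chrom_lengths.items()
    ]
    return tile_regions(pd.concat(frames, ignore_index=True), window=window)


@dataclass
class _ChromMasks:
    """Cumulative base-class counts for O(1) per-tile lookups."""

    cum_cpg_c: np.ndarray      # C positions of CpG dinucleotides
    cum_cpg_base: np.ndarray   # C or G positions belonging to a CpG
    cum_noncpg_cg: np.ndarray  # C or G positions outside CpGs


def _chrom_masks(genome: GenomeSequence, chrom: str) -> _ChromMasks:
    arr = genome.byte_array(chrom)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    cpg_c = np.zeros(len(arr), dtype=bool)
    cpg_c[:-1] = is_c[:-1] & is_g[1:]
    cpg_g = np.zeros(len(arr), dtype=bool)
    cpg_g[1:] = cpg_c[:-1]
    cpg_base = cpg_c | cpg_g
    noncpg_cg = (is_c | is_g) & ~cpg_base

    def cum(mask):
        out = np.zeros(len(mask) + 1, dtype=np.int64)
        np.cumsum(mask, out=out[1:])
        return out

    return _ChromMasks(cum(cpg_c), cum(cpg_base), cum(noncpg_cg))


def _range_counts(cum: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    return cum[ends] - cum[starts]


def tile_stats(
    tiles: pd.DataFrame,
    genome: GenomeSequence,
    stage_frames: dict[str, pd.DataFrame],
    catalog: pd.DataFrame,
    min_cpg: int = MIN_CPG_PER_TILE,
) -> pd.DataFrame:
    """Per-tile CpG counts, C>T densities and weighted methylation per stage.

    * ``cpg_ct_density`` = CpG C>T SNPs in the tile / C+G bases at CpG
      sites in the tile (a CpG straddling the tile edge contributes only
      its in-tile base);
    * ``noncpg_ct_density`` = non-CpG C>T SNPs / non-CpG C+G bases;
    * ``meth_<stage>`` = read-weighted methylation over CpG rows in the
      tile (NaN when the tile has no covered reads in that stage).

    Tiles with fewer than *min_cpg* CpG dinucleotides are dropped.
    """
    out_frames = []
    for chrom, sub in tiles.groupby("Chromosome", sort=True):
        masks = _chrom_masks(genome, chrom)
        starts = sub["Start"].to_numpy(dtype=np.int64)
        ends = sub["End"].to_numpy(dtype=np.int64)
        res = sub.reset_index(drop=True).copy()
        res["cpg_count"] = _range_counts(masks.cum_cpg_c, starts, ends)
        res["cpg_cg_bases"] = _range_counts(masks.cum_cpg_base, starts, ends)
        res["noncpg_cg_bases"] = _range_counts(masks.cum_noncpg_cg, starts, ends)

        cat = catalog[catalog["chrom"] == chrom]
        for col, mtype in (
            ("cpg_ct_snps", MutationType.CPG_C_T.value),
            ("noncpg_ct_snps", MutationType.NONCPG_C_T.value),
        ):
            pos0 = np.sort(cat.loc[cat["mutation_type"] == mtype, "pos"].to_numpy(dtype=np.int64) - 1)
            res[col] = np.searchsorted(pos0, ends) - np.searchsorted(pos0, starts)

        with np.errstate(invalid="ignore", divide="ignore"):
            res["cpg_ct_density"] = res["cpg_ct_snps"] / res["cpg_cg_bases"]
            res["noncpg_ct_density"] = res["noncpg_ct_snps"] / res["noncpg_cg_bases"]

        for stage in STAGES:
            df = stage_frames[stage]
            df = df[(df["chrom"] == chrom) & (df["context"] == "CpG")]
            order = np.argsort(df["pos"].to_numpy(), kind="stable")
            pos0 = df["pos"].to_numpy(dtype=np.int64)[order] - 1
            meth = np.zeros(len(pos0) + 1, dtype=np.int64)
            np.cumsum(df["methylated_reads"].to_numpy()[order], out=meth[1:])
            tot = np.zeros(len(pos0) + 1, dtype=np.int64)
            np.cumsum(df["total_reads"].to_numpy()[order], out=tot[1:])
            lo = np.searchsorted(pos0, starts)
            hi = np.searchsorted(pos0, ends)
            tile_tot = tot[hi] - tot[lo]
            tile_meth = meth[hi] - meth[lo]
            with np.errstate(invalid="ignore", divide="ignore"):
                res[f"meth_{stage}"] = np.where(tile_tot > 0, tile_meth / np.maximum(tile_tot, 1), np.nan)
        out_frames.append(res)

    out = pd.concat(out_frames, ignore_index=True)
    return out[out["cpg_count"] >= min_cpg].reset_index(drop=True)


def region_correlations(
    tile_table: pd.DataFrame,
    group_col: str = "region_class",
    min_tiles: int = MIN_TILES_PER_GROUP,
) -> pd.DataFrame:
    """Spearman rho of weighted methylation vs C>T density per group/stage.

    One row per (group, stage, measure in {CpG, nonCpG}); ties get average
    ranks, p-values from the t transform (scipy). Groups with fewer than
    *min_tiles* usable tiles, or constant vectors, are reported as missing.
    """
    rows = []
    for group, sub in tile_table.groupby(group_col, sort=True):
        for stage in STAGES:
            meth = sub[f"meth_{stage}"].to_numpy(dtype=float)
            for measure, col in (("CpG", "cpg_ct_density"), ("nonCpG", "noncpg_ct_density")):
                dens = sub[col].to_numpy(dtype=float)
                ok = np.isfinite(meth) & np.isfinite(dens)
                rho, p = np.nan, np.nan
                if ok.sum() >= min_tiles:
                    if np.ptp(meth[ok]) == 0 or np.ptp(dens[ok]) == 0:
                        warnings.warn(f"{group}/{stage}/{measure}: constant vector, rho undefined")
                    else:
                        rho, p = stats.spearmanr(meth[ok], dens[ok])
                rows.append((group, stage, measure, int(ok.sum()), rho, p))
    return pd.DataFrame(rows, columns=[group_col, "stage", "measure", "n_tiles", "spearman_rho", "pvalue"])
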