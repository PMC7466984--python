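"""Per-site methylation levels, calls, bins and cross-stage summaries.

The methylation level of a cytosine is the fraction of methylated
(unconverted C) reads among its covered reads; only sites with at least
5 reads enter any analysis. "Methylated" is decided by a one-sided exact
binomial test against a background rate (bisulfite non-conversion /
sequencing error), Benjamini–Hochberg corrected across the sites of a
stage. Methylated sites are further binned into five level groups
(0–20 … 80–100%), and for the cross-stage pattern analysis every level is
coded H (>= 70%), U (< 20%) or M (in between).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from methmut.stages import STAGES

MIN_READS = 5

BIN_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
BIN_LABELS = ("0-20%", "20-40%", "40-60%", "60-80%", "80-100%")
BIN_MIDPOINTS = (0.1, 0.3, 0.5, 0.7, 0.9)

H_THRESHOLD = 0.7
U_THRESHOLD = 0.2


def site_level(methylated_reads, total_reads):
    """Methylation level = methylated / total reads (vectorised).

    Callers must have applied the >= 5 read depth filter; a total below
    5 here is a contract violation, methylated > total an error.
    """
    m = np.asarray(methylated_reads, dtype=float)
    n = np.asarray(total_reads, dtype=float)
    if np.any(n < MIN_READS):
        raise ValueError(f"site_level called with total_reads < {MIN_READS}")
    if np.any(m > n):
        raise ValueError("methylated_reads exceeds total_reads")
    return m / n


def depth_filter(df: pd.DataFrame, min_reads: int = MIN_READS) -> pd.DataFrame:
    """Rows with total_reads >= *min_reads*; excluded count is reported."""
    kept = df[df["total_reads"] >= min_reads].copy()
    return kept


def binomial_pvalues(methylated_reads, total_reads, p0: float) -> np.ndarray:
    """One-sided exact binomial upper-tail p-values.

    P(X >= m) for X ~ Binomial(n, p0): the evidence that a site is
    methylated above the background (non-conversion) rate *p0*.
    """
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    m = np.asarray(methylated_reads, dtype=np.int64)
    n = np.asarray(total_reads, dtype=np.int64)
    return stats.binom.sf(m - 1, n, p0)


def call_methylated(methylated_reads, total_reads, p0: float = 0.01, alpha: float = 0.05):
    """Binomial methylation calls for all sites of one stage.

    Exact one-sided binomial tests against H0: p = p0 (alternative
    greater), Benjamini–Hochberg corrected across all tested sites of the
    stage; a site is called methylated iff its corrected p is below
    *alpha*. Returns ``(calls, pvalues)``; calls is a boolean array.
    """
    p = binomial_pvalues(methylated_reads, total_reads, p0)
    if len(p) == 0:
        return np.zeros(0, dtype=bool), p
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p


def assign_bin(level) -> np.ndarray:
    """Five-group methylation-level bin for methylated-called sites.

    Bins are left-closed, right-open, with the top bin closed at 1.0:
    [0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8), [0.8,1.0].
    """
    lv = np.asarray(level, dtype=float)
    if np.any((lv < 0) | (lv > 1)):
        raise ValueError("methylation level outside [0, 1]")
    idx = np.minimum(np.searchsorted(BIN_EDGES, lv, side="right") - 1, 4)
    return np.asarray(BIN_LABELS, dtype=object)[idx]


def three_state(level) -> np.ndarray:
    """H/M/U code: H iff level >= 0.7, U iff level < 0.2, else M."""
    lv = np.asarray(level, dtype=float)
    if np.any((lv < 0) | (lv > 1)):
        raise ValueError("methylation level outside [0, 1]")
    out = np.full(lv.shape, "M", dtype="U1")
    out[lv >= H_THRESHOLD] = "H"
    out[lv < U_THRESHOLD] = "U"
    return out


def annotate_stage(df: pd.DataFrame, p0: float = 0.01, alpha: float = 0.05,
                   min_reads: int = MIN_READS, merge_strands: bool = False) -> pd.DataFrame:
    """Full per-stage site annotation: depth filter, level, call, bin, state.

    Input is a canonical methylation frame; only CpG-context rows are
    levelled and called (non-CpG rows are dropped here — non-CpG density
    estimates count reference bases, not these rows). With
    ``merge_strands`` the read counts of the two cytosines of one CpG
    (positions p and p+1 on opposite strands) are summed onto the
    plus-strand C before filtering.
    """
    cpg = df[df["context"] == "CpG"].copy()
    if merge_strands:
        site = np.where(cpg["strand"] == "-", cpg["pos"] - 1, cpg["pos"])
        cpg = (
            cpg.assign(pos=site)
            .groupby(["chrom", "pos"], as_index=False)
            .agg(strand=("strand", lambda s: "+"),
                 context=("context", "first"),
                 methylated_reads=("methylated_reads", "sum"),
                 total_reads=("total_reads", "sum"))
        )
    kept = depth_filter(cpg, min_reads)
    kept["level"] = site_level(kept["methylated_reads"], kept["total_reads"])
    calls, pvals = call_methylated(kept["methylated_reads"].to_numpy(),
                                   kept["total_reads"].to_numpy(), p0, alpha)
    kept["call"] = np.where(calls, "methylated", "unmethylated")
    kept["pvalue"] = pvals
    kept["bin"] = assign_bin(kept["level"])
    kept.loc[kept["call"] != "methylated", "bin"] = ""
    kept["three_state"] = three_state(kept["level"])
    return kept.reset_index(drop=True)


def common_sites(stage_frames: dict[str, pd.DataFrame], min_reads: int = MIN_READS) -> pd.DataFrame:
    """Sites covered with >= *min_reads* reads in every one of the 13 stages.

    *stage_frames* maps stage id to a canonical (or annotated) methylation
    frame. Returns a frame indexed by (chrom, pos) with one ``level_<stage>``
    column per stage, sorted by (chrom, pos). Requiring presence of all 13
    stages guards against coverage bias between samples.
    """
    missing = [s for s in STAGES if s not in stage_frames]
    if missing:
        raise ValueError(f"common_sites requires all 13 stages; missing {missing}")

    merged: pd.DataFrame | None = None
    for stage in STAGES:
        df = stage_frames[stage]
        df = df[(df["total_reads"] >= min_reads) & (df["context"] == "CpG")]
        lvl = (df["methylated_reads"] / df["total_reads"]).to_numpy()
        part = pd.DataFrame({
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos"].to_numpy(),
            f"level_{stage}": lvl,
        })
        merged = part if merged is None else merged.merge(part, on=["chrom", "pos"], how="inner")
    merged = merged.sort_values(["chrom", "pos"]).reset_index(drop=True)
    if merged.empty:
        warnings.warn("common-site intersection across the 13 stages is empty")
    return merged


def tile_weighted_methylation(methylated_reads, total_reads) -> float:
    """Read-weighted methylation of a tile: sum(meth) / sum(total).

    This is the weighted methylation level (fraction of methylated C reads
    over all C+T reads in the tile), not the mean of site ratios.
    """
    total = int(np.sum(total_reads))
    if total == 0:
        raise ZeroDivisionError("tile has zero covered reads")
    return float(np.sum(methylated_reads)) / total
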