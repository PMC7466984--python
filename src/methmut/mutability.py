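"""SNP-density mutability statistics at site and pattern level.

Mutability of a set of CpG sites is estimated as SNP density: the number
of distinct sites carrying a CpG-type SNP (C>T, C>A or C>G at the CpG,
either strand) divided by the number of sites in the set. Densities are
computed per methylation category within a stage (all / methylated /
unmethylated / five level bins) and per dynamic methylation pattern (the
13-character H/M/U string of a site across stages).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from methmut.methylome import BIN_LABELS, BIN_MIDPOINTS, three_state
from methmut.stages import STAGES
from methmut.variant_catalog import CPG_TYPES

CPG_TYPE_VALUES = tuple(t.value for t in CPG_TYPES)

PROFILE_CATEGORIES = ("all", "methylated", "unmethylated") + BIN_LABELS


def cpg_snp_sites(catalog: pd.DataFrame, chrom: str | None = None) -> np.ndarray:
    """Distinct canonical CpG site positions carrying a CpG-type SNP.

    Multiple catalog records at one site (both cytosines of the CpG, or
    recurrent alleles) count once: density is per-site probability mass.
    """
    sub = catalog[catalog["mutation_type"].isin(CPG_TYPE_VALUES)]
    if chrom is not None:
        sub = sub[sub["chrom"] == chrom]
    return np.unique(sub["cpg_site_pos"].to_numpy(dtype=np.int64))


def snp_density(site_positions, snp_sites) -> tuple[int, int, float]:
    """(n_sites, n_snps, density) for a set of CpG site positions.

    *snp_sites* is the deduplicated array from :func:`cpg_snp_sites`;
    a site counts as mutated iff its position is in that array.
    """
    pos = np.unique(np.asarray(site_positions, dtype=np.int64))
    n_sites = len(pos)
    if n_sites == 0:
        raise ZeroDivisionError("no sites in category")
    n_snps = int(np.isin(pos, snp_sites).sum())
    return n_sites, n_snps, n_snps / n_sites


@dataclass
class StageBinProfile:
    """Per-category SNP density table for one stage."""

    stage_id: str
    table: pd.DataFrame  # columns: category, n_sites, n_snps, density

    def density(self, category: str) -> float:
        row = self.table[self.table["category"] == category]
        if row.empty:
            raise KeyError(f"category {category!r} absent from profile ({self.stage_id})")
        return float(row["density"].iloc[0])


def stage_bin_profile(annotated: pd.DataFrame, catalog: pd.DataFrame,
                      stage_id: str, chrom: str | None = None) -> StageBinProfile:
    """SNP density per methylation category for one annotated stage frame.

    Categories: all covered CpGs, methylated (binomial call), unmethylated,
    and the five level bins over methylated sites. Empty categories are
    dropped with a warning rather than reported as 0/0.
    """
    if chrom is None:
        chroms = annotated["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError("pass chrom= for multi-chromosome frames")
        chrom = chroms[0]
    snps = cpg_snp_sites(catalog, chrom=chrom)
    sub = annotated[annotated["chrom"] == chrom]

    def subset_positions(mask) -> np.ndarray:
        return sub.loc[mask, "pos"].to_numpy(dtype=np.int64)

    rows = []
    selectors = {
        "all": np.ones(len(sub), dtype=bool),
        "methylated": (sub["call"] == "methylated").to_numpy(),
        "unmethylated": (sub["call"] == "unmethylated").to_numpy(),
    }
    meth = (sub["call"] == "methylated").to_numpy()
    for label in BIN_LABELS:
        selectors[label] = meth & (sub["bin"] == label).to_numpy()
    for category, mask in selectors.items():
        pos = subset_positions(mask)
        if len(pos) == 0:
            warnings.warn(f"{stage_id}: category {category!r} has no sites; dropped")
            continue
        n_sites, n_snps, density = snp_density(pos, snps)
        rows.append((category, n_sites, n_snps, density))
    return StageBinProfile(stage_id, pd.DataFrame(rows, columns=["category", "n_sites", "n_snps", "density"]))


def bin_trend_correlation(profile: StageBinProfile,
                          midpoints=BIN_MIDPOINTS) -> tuple[float, float]:
    """Pearson correlation of the five bin densities against bin midpoints.

    Two-sided p from the t transform with n = 5. All five bins must be
    present; constant densities make r undefined (error).
    """
    missing = [b for b in BIN_LABELS if b not in set(profile.table["category"])]
    if missing:
        raise ValueError(f"bins missing from profile: {missing}")
    dens = np.array([profile.density(b) for b in BIN_LABELS])
    if np.ptp(dens) == 0:
        raise ValueError("bin densities are constant; Pearson r undefined")
    r, p = stats.pearsonr(np.asarray(midpoints, dtype=float), dens)
    return float(r), float(p)


def meth_vs_unmeth_test(profile: StageBinProfile, correction: bool = True) -> tuple[float, float]:
    """Chi-squared test of SNP occurrence, methylated vs unmethylated sites.

    2x2 table {methylated, unmethylated} x {SNP, no SNP}, Yates continuity
    correction by default. Expected cells below 1 trigger a warning
    suggesting an exact test.
    """
    try:
        m = profile.table.set_index("category").loc["methylated"]
        u = profile.table.set_index("category").loc["unmethylated"]
    except KeyError as exc:
        raise ValueError(f"profile lacks category {exc} for the 2x2 test") from exc
    table = np.array([
        [m["n_snps"], m["n_sites"] - m["n_snps"]],
        [u["n_snps"], u["n_sites"] - u["n_snps"]],
    ], dtype=float)
    if np.any(table.sum(axis=1) == 0):
        raise ValueError("empty methylated or unmethylated group")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=correction)
    if np.any(expected < 1):
        warnings.warn("expected cell count < 1; consider Fisher's exact test")
    return float(chi2), float(p)


def enumerate_patterns(common: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Dynamic methylation pattern (13-char H/M/U code) for each common site.

    *common* is the common-site frame with ``level_<stage>`` columns in the
    canonical stage order. Returns the frame with a ``pattern`` column and
    the number of distinct codes.
    """
    cols = [f"level_{s}" for s in STAGES]
    missing = [c for c in cols if c not in common.columns]
    if missing:
        raise ValueError(f"common-site frame missing stage levels: {missing}")
    levels = common[cols].to_numpy(dtype=float)
    if np.isnan(levels).any():
        raise ValueError("missing methylation level at a common site")
    codes = three_state(levels)  # (n_sites, 13)
    patterns = np.array(["".join(row) for row in codes], dtype=object)
    out = common.copy()
    out["pattern"] = patterns
    return out, int(pd.unique(patterns).size)


def pattern_mutability(patterned: pd.DataFrame, catalog: pd.DataFrame,
                       min_snps: int = 10, top_k: int = 20) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP density per dynamic pattern, with the ranked top-k extraction.

    The full table keeps every pattern; the ranking keeps only patterns
    with at least *min_snps* CpG SNPs, ordered by descending density, ties
    broken by descending n_sites then lexicographic code (determinism).
    Returns ``(full_table, top_k_table)``.
    """
    rows = []
    for chrom, sub in patterned.groupby("chrom", sort=True):
        snps = cpg_snp_sites(catalog, chrom=chrom)
        mutated = np.isin(sub["pos"].to_numpy(dtype=np.int64), snps)
        grouped = pd.DataFrame({"pattern": sub["pattern"].to_numpy(), "mutated": mutated})
        agg = grouped.groupby("pattern").agg(n_sites=("mutated", "size"), n_snps=("mutated", "sum"))
        rows.append(agg)
    full = pd.concat(rows).groupby(level=0).sum().reset_index()
    full["density"] = full["n_snps"] / full["n_sites"]
    full = full.sort_values(
        ["density", "n_sites", "pattern"], ascending=[False, False, True]
    ).reset_index(drop=True)
    ranked = full[full["n_snps"] >= min_snps].reset_index(drop=True)
    if ranked.empty:
        warnings.warn(f"no pattern reaches {min_snps} CpG SNPs; ranking is empty")
    return full, ranked.head(top_k)
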