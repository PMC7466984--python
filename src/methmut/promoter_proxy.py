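"""Promoter CpG observed/expected ratio, SNP density, and expression proxies.

CpG O/E — observed CpG frequency over the product of C and G frequencies,
(N_CpG × L) / (N_C × N_G) — is depressed by historical methylation-driven
CpG loss and therefore serves as an evolutionary-timescale readout of the
germline CpG mutation rate of a promoter. Promoter CpG SNP density is the
contemporary analogue (rare CpG SNPs over C/G bases at promoter CpGs).
Because promoter methylation suppresses transcription, per-tissue Spearman
correlations of gene expression with either statistic provide indirect
evidence about methylation-mutability coupling: tissues whose expression
anti-correlates with promoter mutability most strongly are expected to be
germline.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from methmut.genomic_io import GenomeSequence
from methmut.regional_association import promoter_intervals
from methmut.variant_catalog import CPG_TYPES

CPG_TYPE_VALUES = tuple(t.value for t in CPG_TYPES)

MIN_SHARED_GENES = 50
BOTTOM_K = 20


def cpg_oe(sequence: str, denominator: str = "length") -> float:
    """Observed/expected CpG ratio of a sequence.

    (N_CpG × L) / (N_C × N_G), with N bases excluded from all counts and
    from L. ``denominator="length-1"`` uses L−1 (the count of dinucleotide
    slots) instead of L. Returns NaN (with a warning) when the sequence
    has no C or no G.
    """
    seq = sequence.upper()
    n_n = seq.count("N")
    L = len(seq) - n_n
    if L < 2:
        raise ValueError("sequence shorter than 2 informative bases")
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cpg = seq.count("CG")
    if n_c == 0 or n_g == 0:
        warnings.warn("no C or no G in sequence; CpG O/E undefined")
        return float("nan")
    denom_len = L if denominator == "length" else L - 1
    return (n_cpg * denom_len) / (n_c * n_g)


def promoter_stats(
    genes,
    genome: GenomeSequence,
    catalog: pd.DataFrame,
    snp_types=CPG_TYPE_VALUES,
) -> pd.DataFrame:
    """Per-gene promoter CpG O/E and CpG SNP density.

    The promoter is the strand-aware −1000/+200 window around the TSS.
    SNP density = CpG-context SNPs of the given types in the promoter over
    the number of C and G bases at CpG dinucleotides within it (default:
    all three CpG types). Genes whose promoter has no CpG (or no C/G) are
    dropped with a warning.
    """
    rows = []
    cat = catalog[catalog["mutation_type"].isin(snp_types)]
    for g in genes:
        if not g.name:
            raise ValueError("genes must be named for promoter statistics")
        prom = promoter_intervals([g], genome.lengths)
        if prom.empty:
            warnings.warn(f"{g.name}: promoter falls outside the chromosome; dropped")
            continue
        chrom, start, end = prom.iloc[0][["Chromosome", "Start", "End"]]
        seq = genome.slice(chrom, int(start), int(end))
        n_cpg = seq.count("CG")
        if n_cpg == 0:
            warnings.warn(f"{g.name}: promoter has no CpG; dropped")
            continue
        # C/G bases belonging to CpG dinucleotides fully inside the promoter
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_c, is_g = arr == ord("C"), arr == ord("G")
        cpg_c = np.zeros(len(arr), dtype=bool)
        cpg_c[:-1] = is_c[:-1] & is_g[1:]
        cpg_base_count = int(cpg_c.sum() * 2)
        sub = cat[(cat["chrom"] == chrom) & (cat["pos"] >= start + 1) & (cat["pos"] <= end)]
        n_snps = int(sub["cpg_site_pos"].nunique())
        try:
            oe = cpg_oe(seq)
        except ValueError:
            warnings.warn(f"{g.name}: promoter too short for CpG O/E; dropped")
            continue
        rows.append({
            "gene": g.name, "chrom": chrom, "start": int(start), "end": int(end),
            "length": int(end - start), "n_cpg": n_cpg,
            "n_c": int(is_c.sum()), "n_g": int(is_g.sum()),
            "cpg_oe": oe,
            "cpg_snp_density": n_snps / cpg_base_count,
        })
    return pd.DataFrame(rows)


def expression_correlations(
    expression: pd.DataFrame,
    gene_statistic: pd.Series,
    tissue_classes: pd.DataFrame,
    min_shared_genes: int = MIN_SHARED_GENES,
    bottom_k: int = BOTTOM_K,
) -> tuple[pd.DataFrame, int]:
    """Per-tissue Spearman correlation of expression with a promoter statistic.

    Parameters
    ----------
    expression : genes × tissues frame of expression intensities.
    gene_statistic : per-gene promoter statistic (SNP density or CpG O/E),
        indexed by gene id; the gene sets are intersected.
    tissue_classes : frame with columns ``tissue``, ``tissue_class`` and
        ``germline`` (bool).

    Returns the per-tissue table sorted ascending by rho (columns tissue,
    tissue_class, germline, n_genes, rho, pvalue, rank) and the number of
    germline tissues among the *bottom_k* lowest correlations. Tissues
    sharing fewer than *min_shared_genes* genes with the statistic are
    skipped with a warning.
    """
    classes = tissue_classes.set_index("tissue")
    rows = []
    for tissue in expression.columns:
        expr = expression[tissue].dropna()
        shared = expr.index.intersection(gene_statistic.dropna().index)
        if len(shared) < min_shared_genes:
            warnings.warn(f"{tissue}: only {len(shared)} shared genes; skipped")
            continue
        rho, p = stats.spearmanr(expr.loc[shared], gene_statistic.loc[shared])
        rows.append({
            "tissue": tissue,
            "tissue_class": classes.loc[tissue, "tissue_class"],
            "germline": bool(classes.loc[tissue, "germline"]),
            "n_genes": len(shared),
            "rho": float(rho),
            "pvalue": float(p),
        })
    if not rows:
        raise ValueError(
            f"no tissue shares >= {min_shared_genes} genes with the promoter statistic"
        )
    table = pd.DataFrame(rows).sort_values("rho", ascending=True).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    n_germline_bottom = int(table.head(bottom_k)["germline"].sum())
    return table, n_germline_bottom
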