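"""Rare-variant filtering and the 9-way mutation-type classification.

Rare autosomal SNPs (allele frequency < 0.1%, variant quality exactly 100)
stand in for de novo germline mutations. Each retained SNP is classified by
its reference context into one of nine types: three CpG types
(C>T, C>A, C>G at a CpG dinucleotide, with the purine-strand change
collapsed onto the pyrimidine strand, e.g. G>A == C>T) and six non-CpG
types (C>T, C>A, C>G, T>C, T>G, T>A at CHH/CHG context).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from methmut.genomic_io import GenomeSequence, RawVariant


class MutationType(str, Enum):
    CPG_C_T = "CpG_C>T"
    CPG_C_A = "CpG_C>A"
    CPG_C_G = "CpG_C>G"
    NONCPG_C_T = "nonCpG_C>T"
    NONCPG_C_A = "nonCpG_C>A"
    NONCPG_C_G = "nonCpG_C>G"
    NONCPG_T_C = "nonCpG_T>C"
    NONCPG_T_G = "nonCpG_T>G"
    NONCPG_T_A = "nonCpG_T>A"
    UNCLASSIFIED = "UNCLASSIFIED"


CPG_TYPES = (MutationType.CPG_C_T, MutationType.CPG_C_A, MutationType.CPG_C_G)

#: purine-strand change -> pyrimidine-strand change
_COLLAPSE = {
    ("G", "A"): ("C", "T"),
    ("G", "T"): ("C", "A"),
    ("G", "C"): ("C", "G"),
    ("A", "G"): ("T", "C"),
    ("A", "C"): ("T", "G"),
    ("A", "T"): ("T", "A"),
}

_DEFAULT_AF_MAX = 0.001
_DEFAULT_QUAL = 100.0

FILTER_RULES = (
    "symbolic",
    "indel",
    "multiallelic",
    "non_autosomal",
    "frequency_unknown",
    "allele_frequency",
    "quality",
)


@dataclass
class FilterReport:
    """Counts of variants removed per rule, in rule order; additive."""

    removed: dict[str, int] = field(default_factory=lambda: {r: 0 for r in FILTER_RULES})
    retained: int = 0

    @property
    def total(self) -> int:
        return self.retained + sum(self.removed.values())

    def to_dict(self) -> dict:
        return {"removed": dict(self.removed), "retained": self.retained, "total": self.total}


def filter_variants(
    raw,
    autosome_names,
    af_max: float = _DEFAULT_AF_MAX,
    qual: float = _DEFAULT_QUAL,
) -> tuple[pd.DataFrame, FilterReport]:
    """Filter a stream of :class:`RawVariant` to the rare-SNP proxy set.

    A variant is removed by the first rule it violates, in this order:
    symbolic/structural alt, indel (ref or alt longer than one base),
    multi-allelic, non-autosomal chromosome, unknown allele frequency,
    allele frequency >= *af_max*, quality != *qual*.

    Returns the retained records as a DataFrame
    (chrom, pos, ref, alt, allele_frequency, qual) and a
    :class:`FilterReport` whose categories plus the retained count sum to
    the input count.
    """
    autosomes = set(autosome_names)
    report = FilterReport()
    rows = []
    for v in raw:
        if v.is_symbolic:
            report.removed["symbolic"] += 1
            continue
        if len(v.ref) != 1 or any(len(a) != 1 for a in v.alts):
            report.removed["indel"] += 1
            continue
        if len(v.alts) != 1:
            report.removed["multiallelic"] += 1
            continue
        if v.chrom not in autosomes:
            report.removed["non_autosomal"] += 1
            continue
        if v.frequency_unknown or not v.allele_frequencies:
            report.removed["frequency_unknown"] += 1
            continue
        af = v.allele_frequencies[0]
        if not af < af_max:
            report.removed["allele_frequency"] += 1
            continue
        if v.qual is None or v.qual != qual:
            report.removed["quality"] += 1
            continue
        report.retained += 1
        rows.append((v.chrom, v.pos, v.ref, v.alts[0], af, float(v.qual)))
    catalog = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "allele_frequency", "qual"]
    )
    if len(catalog):
        catalog["pos"] = catalog["pos"].astype(np.int64)
    return catalog, report


def classify_mutation(chrom: str, pos: int, ref: str, alt: str, genome: GenomeSequence) -> MutationType:
    """Classify one SNP by reference context.

    CpG context holds iff the reference has C at *pos* followed by G, or
    G at *pos* preceded by C (the two cytosines of one CpG dinucleotide).
    Purine-strand changes are collapsed to the pyrimidine strand. A needed
    neighbour that is N or off the chromosome end yields UNCLASSIFIED.
    """
    length = len(genome.sequences[chrom])
    if not (1 <= pos <= length):
        raise IndexError(f"{chrom}:{pos} outside chromosome (length {length})")
    ref_base = genome.base(chrom, pos)
    if ref_base != ref:
        raise ValueError(f"reference mismatch at {chrom}:{pos}: genome {ref_base}, variant {ref}")

    pyr_ref, pyr_alt = _COLLAPSE.get((ref, alt), (ref, alt))
    if pyr_ref not in ("C", "T"):
        return MutationType.UNCLASSIFIED  # e.g. N reference

    if pyr_ref == "C":
        # CpG membership needs the neighbour on the G side.
        if ref == "C":
            neighbour = genome.base(chrom, pos + 1) if pos + 1 <= length else None
        else:  # ref == "G": the G of a possible CpG; look left for the C
            neighbour = genome.base(chrom, pos - 1) if pos - 1 >= 1 else None
        if neighbour is None or neighbour == "N":
            return MutationType.UNCLASSIFIED
        expected = "G" if ref == "C" else "C"
        is_cpg = neighbour == expected
        key = {"T": "C_T", "A": "C_A", "G": "C_G"}[pyr_alt]
        return MutationType[("CPG_" if is_cpg else "NONCPG_") + key]

    # pyrimidine-strand T mutations are non-CpG by definition
    key = {"C": "T_C", "G": "T_G", "A": "T_A"}[pyr_alt]
    return MutationType["NONCPG_" + key]


def cpg_site_position(pos: int, ref: str) -> int:
    """Canonical site position (the C of the CpG) for a CpG-context SNP.

    A CpG dinucleotide carries two mutable cytosines — the plus-strand C
    and the minus-strand C (the G one base to the right). Both map to the
    same site, anchored at the plus-strand C.
    """
    return pos if ref == "C" else pos - 1


def classify_catalog(catalog: pd.DataFrame, genome: GenomeSequence) -> tuple[pd.DataFrame, int]:
    """Vectorised classification of a filtered catalog.

    Adds ``mutation_type``, ``cpg_context`` and, for CpG-context SNPs, the
    canonical ``cpg_site_pos`` (C of the dinucleotide). Returns the frame
    and the count of UNCLASSIFIED records (N neighbours / chromosome
    edges), which stay in the frame for auditability.
    """
    if catalog.empty:
        out = catalog.copy()
        out["mutation_type"] = pd.Series(dtype=object)
        out["cpg_context"] = pd.Series(dtype=object)
        out["cpg_site_pos"] = pd.Series(dtype="Int64")
        return out, 0

    types = np.array(
        [
            classify_mutation(chrom, int(pos), ref, alt, genome).value
            for chrom, pos, ref, alt in zip(
                catalog["chrom"], catalog["pos"], catalog["ref"], catalog["alt"]
            )
        ],
        dtype=object,
    )

    out = catalog.copy()
    out["mutation_type"] = types
    out["cpg_context"] = np.where(
        pd.Series(types).str.startswith("CpG").to_numpy(), "CpG",
        np.where(pd.Series(types).to_numpy() == MutationType.UNCLASSIFIED.value, "unknown", "nonCpG"),
    )
    is_cpg = out["cpg_context"].to_numpy() == "CpG"
    sp = np.where(
        out["ref"].to_numpy() == "C", out["pos"].to_numpy(), out["pos"].to_numpy() - 1
    )
    site_pos = np.where(is_cpg, sp, -1)
    out["cpg_site_pos"] = site_pos
    n_unclassified = int((out["mutation_type"] == MutationType.UNCLASSIFIED.value).sum())
    return out, n_unclassified


def type_proportions(catalog: pd.DataFrame) -> tuple[dict[str, float], int]:
    """Fraction of each of the 9 mutation types among classified SNPs.

    UNCLASSIFIED records are excluded from the denominator and returned as
    a separate count. Fractions sum to 1. Empty (or all-UNCLASSIFIED)
    catalogs are an error.
    """
    if catalog.empty:
        raise ValueError("empty catalog")
    mt = catalog["mutation_type"]
    n_unclassified = int((mt == MutationType.UNCLASSIFIED.value).sum())
    classified = mt[mt != MutationType.UNCLASSIFIED.value]
    if classified.empty:
        raise ValueError("no classified SNPs in catalog")
    props = (classified.value_counts() / len(classified)).to_dict()
    return props, n_unclassified
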