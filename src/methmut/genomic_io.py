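"""Readers and writers for the standard genomic formats the pipeline touches.

One coordinate convention throughout the package: intervals are 0-based
half-open (BED-style); point positions (VCF records, methylation rows) are
1-based. Conversion happens only at I/O boundaries, never downstream.

Canonical methylation table dialect (TSV, ``#``-prefixed provenance
comments, then a header line)::

    chrom  pos  strand  context  methylated_reads  total_reads

with ``pos`` the 1-based position of the cytosine and ``context`` one of
CpG/CHG/CHH. Adapters convert Bismark cytosine (CX) reports and bedMethyl
into this dialect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

VALID_CONTEXTS = ("CpG", "CHG", "CHH")

METH_COLUMNS = ["chrom", "pos", "strand", "context", "methylated_reads", "total_reads"]


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - ., got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


class GenomeSequence:
    """Uppercased reference sequences with a parallel soft-mask.

    Lowercase (soft-masked) input bases are uppercased for all lookups but
    remembered in ``mask`` (True = was lowercase); repeat handling in this
    pipeline comes from the repeat BED track, not from the mask.
    """

    def __init__(self, sequences: dict[str, str], masks: dict[str, np.ndarray] | None = None):
        self.sequences: dict[str, str] = {}
        self.masks: dict[str, np.ndarray] = {}
        for name, seq in sequences.items():
            if len(seq) == 0:
                raise ValueError(f"zero-length sequence for {name!r}")
            upper = seq.upper()
            bad = set(upper) - set("ACGTN")
            if bad:
                raise ValueError(f"non-nucleotide characters in {name!r}: {sorted(bad)}")
            self.sequences[name] = upper
            if masks is not None and name in masks:
                self.masks[name] = np.asarray(masks[name], dtype=bool)
            else:
                self.masks[name] = np.frombuffer(seq.encode(), dtype=np.uint8) >= ord("a")

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def base(self, chrom: str, pos1: int) -> str:
        """Reference base at 1-based position *pos1*."""
        seq = self.sequences[chrom]
        if not (1 <= pos1 <= len(seq)):
            raise IndexError(f"position {pos1} outside {chrom} (length {len(seq)})")
        return seq[pos1 - 1]

    def slice(self, chrom: str, start0: int, end0: int) -> str:
        """Subsequence on 0-based half-open coordinates; bounds are checked."""
        seq = self.sequences[chrom]
        if start0 < 0 or end0 > len(seq) or end0 <= start0:
            raise IndexError(f"[{start0}, {end0}) outside {chrom} (length {len(seq)})")
        return seq[start0:end0]

    def byte_array(self, chrom: str) -> np.ndarray:
        """Sequence as a uint8 array of ASCII codes (vectorised lookups)."""
        return np.frombuffer(self.sequences[chrom].encode(), dtype=np.uint8)


@dataclass
class RawVariant:
    """One VCF record before filtering/classification.

    ``pos`` is 1-based. Multi-allelic records keep all alts here; splitting
    or rejecting them is the variant_catalog module's job.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    allele_frequencies: tuple[float, ...] = ()
    is_symbolic: bool = False
    frequency_unknown: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; the original lowercase (soft-mask) state is
    preserved as a boolean mask. Duplicate record names and zero-length
    records are errors.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq)
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeSequence(sequences)


def write_fasta(path, genome: GenomeSequence, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path):
    """Yield :class:`RawVariant` from a VCF 4.x file (plain or bgzipped).

    Allele frequencies are resolved in this order: INFO/AF, else AC/AN,
    else the record is flagged ``frequency_unknown`` (never silently
    dropped). Symbolic/structural alts are flagged, not parsed further.
    """
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alts = tuple(a if a is not None else "." for a in (rec.alts or ()))
            symbolic = any(
                ("<" in a) or (">" in a) or ("[" in a) or ("]" in a) or a == "*"
                or not set(a) <= set("ACGTN")
                for a in alts
            ) or not alts
            afs: tuple[float, ...] = ()
            unknown = False
            info = rec.info
            if "AF" in info:
                raw = info["AF"]
                afs = tuple(float(x) for x in (raw if isinstance(raw, tuple) else (raw,)))
            elif "AC" in info and "AN" in info:
                an = float(info["AN"])
                raw = info["AC"]
                acs = raw if isinstance(raw, tuple) else (raw,)
                if an > 0:
                    afs = tuple(float(ac) / an for ac in acs)
                else:
                    unknown = True
            else:
                unknown = True
            yield RawVariant(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alts=alts,
                qual=rec.qual,
                allele_frequencies=afs,
                is_symbolic=symbolic,
                frequency_unknown=unknown,
            )


# ---------------------------------------------------------------------------
# Methylation tables


def _validate_methylation_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    if (df["total_reads"] < 0).any() or (df["methylated_reads"] < 0).any():
        bad = df.index[(df["total_reads"] < 0) | (df["methylated_reads"] < 0)][0]
        raise ValueError(f"{source}: negative read count at row {bad}")
    over = df["methylated_reads"] > df["total_reads"]
    if over.any():
        row = df.loc[over].iloc[0]
        raise ValueError(
            f"{source}: methylated_reads > total_reads at "
            f"{row['chrom']}:{row['pos']} ({row['methylated_reads']} > {row['total_reads']})"
        )
    unknown = ~df["context"].isin(VALID_CONTEXTS)
    if unknown.any():
        bad = df.loc[unknown, "context"].iloc[0]
        raise ValueError(f"{source}: unknown cytosine context {bad!r}")
    return df


def read_methylation_table(path, stage_id: str | None = None, dialect: str = "canonical") -> pd.DataFrame:
    """Read a per-cytosine methylation table into the canonical frame.

    Parameters
    ----------
    path : str or file-like
        Input table.
    stage_id : str, optional
        If given, stored in a ``stage_id`` column.
    dialect : {"canonical", "bismark_cx", "bedmethyl"}
        Input dialect. Bismark CX reports
        (chrom, 1-based pos, strand, count_methylated, count_unmethylated,
        context, trinucleotide) and bedMethyl
        (9 BED fields + coverage + percent methylated, 0-based start)
        are converted to the canonical layout; bedMethyl 0-based starts
        become 1-based positions.

    Returns
    -------
    pandas.DataFrame
        Columns ``chrom, pos, strand, context, methylated_reads,
        total_reads`` (+ ``stage_id``). Non-CpG rows are retained but carry
        their context flag; downstream CpG analyses select on it.
    """
    if dialect == "canonical":
        df = pd.read_csv(
            path, sep="\t", comment="#",
            dtype={"chrom": str, "pos": np.int64, "strand": str, "context": str,
                   "methylated_reads": np.int64, "total_reads": np.int64},
        )
        missing = [c for c in METH_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"canonical methylation table missing columns {missing}")
        df = df[METH_COLUMNS]
    elif dialect == "bismark_cx":
        raw = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "pos", "strand", "count_meth", "count_unmeth", "context", "tri"],
            dtype={"chrom": str, "pos": np.int64, "strand": str,
                   "count_meth": np.int64, "count_unmeth": np.int64, "context": str},
        )
        context = raw["context"].replace({"CG": "CpG"})
        df = pd.DataFrame({
            "chrom": raw["chrom"], "pos": raw["pos"], "strand": raw["strand"],
            "context": context,
            "methylated_reads": raw["count_meth"],
            "total_reads": raw["count_meth"] + raw["count_unmeth"],
        })
    elif dialect == "bedmethyl":
        raw = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "name", "score", "strand",
                   "thick_start", "thick_end", "rgb", "coverage", "pct_meth"],
            dtype={"chrom": str, "start": np.int64, "coverage": np.int64},
        )
        meth = np.rint(raw["coverage"] * raw["pct_meth"] / 100.0).astype(np.int64)
        df = pd.DataFrame({
            "chrom": raw["chrom"],
            "pos": raw["start"] + 1,  # 0-based start -> 1-based cytosine
            "strand": raw["strand"],
            "context": "CpG",
            "methylated_reads": meth,
            "total_reads": raw["coverage"],
        })
    else:
        raise ValueError(f"unknown methylation dialect {dialect!r}")

    df = _validate_methylation_frame(df, str(path))
    if stage_id is not None:
        df["stage_id"] = stage_id
    return df


def write_methylation_table(path, df: pd.DataFrame, provenance: str | None = None) -> None:
    """Write a canonical methylation TSV with provenance comments."""
    with open(path, "w") as fh:
        fh.write("# methmut canonical methylation table\n")
        if provenance:
            for line in provenance.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, columns=METH_COLUMNS)


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> list[Interval]:
    """Read BED3+ into a list of 0-based half-open :class:`Interval`.

    Column 4 (name) and column 6 (strand) are honoured when present;
    ``end <= start`` is an error.
    """
    intervals: list[Interval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line has fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{ln}: end <= start ({start}, {end})")
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            intervals.append(Interval(chrom, start, end, strand, name))
    return intervals


def write_bed(path, intervals, provenance: str | None = None) -> None:
    with open(path, "w") as fh:
        if provenance:
            for line in provenance.splitlines():
                fh.write(f"# {line}\n")
        for iv in intervals:
            if iv.name or iv.strand != ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def intervals_to_frame(intervals) -> pd.DataFrame:
    """Intervals as a pyranges-style frame (Chromosome/Start/End/Strand)."""
    return pd.DataFrame(
        {
            "Chromosome": [iv.chrom for iv in intervals],
            "Start": [iv.start for iv in intervals],
            "End": [iv.end for iv in intervals],
            "Strand": [iv.strand for iv in intervals],
            "Name": [iv.name for iv in intervals],
        }
    )
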