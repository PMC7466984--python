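"""Shared locations and config for the numbered analysis drivers.

The drivers run the default synthetic study end to end: 01 simulates the
inputs under scratch/analysis/sim, 02-07 run the pipeline stages and
write their tables under results/analysis. Rerunning any driver with the
same seed reproduces its outputs byte for byte.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from methmut import pipeline as pl
from methmut.stages import STAGES

ROOT = Path(__file__).resolve().parent.parent
SIM_DIR = ROOT / "scratch" / "analysis" / "sim"
OUT_DIR = ROOT / "results" / "analysis"


def parse_seed(description: str) -> int:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    return parser.parse_args().seed


def pipeline_config(seed: int) -> pl.PipelineConfig:
    if not (SIM_DIR / "genome.fa").exists():
        raise SystemExit("run analysis/01_simulate.py first (no simulated study found)")
    return pl.PipelineConfig(
        outdir=str(OUT_DIR),
        fasta=str(SIM_DIR / "genome.fa"),
        vcf=str(SIM_DIR / "variants.vcf"),
        methylomes={s: str(SIM_DIR / f"methylome_{s}.tsv") for s in STAGES},
        genes_bed=str(SIM_DIR / "genes.bed"),
        exons_bed=str(SIM_DIR / "exons.bed"),
        cgis_bed=str(SIM_DIR / "cgis.bed"),
        enhancers_bed=str(SIM_DIR / "enhancers.bed"),
        repeats_bed=str(SIM_DIR / "repeats.bed"),
        expression_tsv=str(SIM_DIR / "expression.tsv"),
        tissue_classes_tsv=str(SIM_DIR / "tissue_classes.tsv"),
        seed=seed,
    )
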