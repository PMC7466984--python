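"""Shared fixtures: handcrafted miniature data and cached simulator runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methmut import synthetic_data as sd
from methmut.genomic_io import GenomeSequence
from methmut.stages import STAGES


@pytest.fixture(scope="session")
def tiny_genome() -> GenomeSequence:
    #            123456789012345678901234
    return GenomeSequence({"chr1": "ACGTACGATCGATACGTTTACGCA"})


@pytest.fixture(scope="session")
def sim_small():
    """One-cassette (100 kb) simulated study, shared read-only."""
    cfg = sd.SimConfig(seed=11)
    cfg.genome.chrom_length = 100_000
    genome, truth, methylomes, variants, tracks, expr, tissue_df = sd.simulate_all(cfg)
    return dict(cfg=cfg, genome=genome, truth=truth, methylomes=methylomes,
                variants=variants, tracks=tracks, expr=expr, tissue_df=tissue_df)


@pytest.fixture(scope="session")
def sim_small_paths(sim_small, tmp_path_factory):
    """The same study written to disk for I/O and pipeline tests."""
    outdir = tmp_path_factory.mktemp("sim_small")
    s = sim_small
    paths = sd.write_outputs(outdir, s["cfg"], s["genome"], s["truth"], s["methylomes"],
                             s["variants"], s["tracks"], s["expr"], s["tissue_df"])
    return paths


@pytest.fixture(scope="session")
def small_catalog(sim_small):
    """Classified rare-SNP catalog of the small study (clean records only)."""
    from methmut import variant_catalog as vc

    v = sim_small["variants"]
    snp = v[v["kind"] == "snp"]
    cat = snp[(snp["af"] < 1e-3) & (snp["qual"] == 100.0)][["chrom", "pos", "ref", "alt"]]
    cat, _ = vc.classify_catalog(cat.reset_index(drop=True), sim_small["genome"])
    return cat


def make_stage_frames(levels: np.ndarray, positions=None, depth: int = 10) -> dict[str, pd.DataFrame]:
    """Canonical frames for all 13 stages from an (n_sites, 13) level matrix."""
    levels = np.asarray(levels, dtype=float)
    n = levels.shape[0]
    pos = np.asarray(positions) if positions is not None else np.arange(1, n + 1) * 10
    frames = {}
    for j, stage in enumerate(STAGES):
        meth = np.rint(levels[:, j] * depth).astype(int)
        frames[stage] = pd.DataFrame({
            "chrom": "chr1", "pos": pos, "strand": "+", "context": "CpG",
            "methylated_reads": meth, "total_reads": depth,
        })
    return frames
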