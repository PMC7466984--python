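"""Simulate the default synthetic study: 1 Mb genome, 13 stage methylomes
at 15x coverage, a variant catalog with a causal sperm-stage methylation
effect (beta = 0.15) plus filter-exercising contamination, annotation
tracks and a 40-tissue expression matrix."""

from common import SIM_DIR, parse_seed

from methmut import synthetic_data as sd


def main() -> None:
    seed = parse_seed(__doc__)
    cfg = sd.SimConfig(seed=seed)
    results = sd.simulate_all(cfg)
    genome, truth, methylomes, variants, *_ = results
    sd.write_outputs(SIM_DIR, cfg, *results)
    n_cpg = sum(len(p) for p in truth.cpg_positions.values())
    print(f"simulated {cfg.genome.chrom_length:,} bp with {n_cpg:,} CpGs "
          f"({int(sum(m.sum() for m in truth.island_mask.values())):,} in CGIs)")
    print(f"emitted {len(variants):,} variant records "
          f"({int(sum(m.sum() for m in truth.mutated.values())):,} CpG-site mutations)")
    print(f"study written to {SIM_DIR}")


if __name__ == "__main__":
    main()
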