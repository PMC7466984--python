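"""Dynamic methylation patterns: 13-character H/M/U codes over the common
sites, SNP density per pattern, and the top-20 mutable patterns (only
patterns with >= 10 CpG SNPs are ranked)."""

from common import OUT_DIR, parse_seed, pipeline_config

from methmut import pipeline as pl


def main() -> None:
    cfg = pipeline_config(parse_seed(__doc__))
    full, top, n_unique = pl.run_patterns(cfg)
    print(f"{n_unique:,} unique patterns over {int(full['n_sites'].sum()):,} common sites")
    if len(top):
        sperm_h = top["pattern"].str[0].eq("H").mean()
        print(f"top-{len(top)} ranked patterns: sperm position is H in {100 * sperm_h:.0f}%")
    else:
        print("no pattern reached the 10-SNP ranking floor at this scale")
    print(f"tables written to {OUT_DIR / 'pattern_mutability.tsv'} and pattern_top.tsv")


if __name__ == "__main__":
    main()
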