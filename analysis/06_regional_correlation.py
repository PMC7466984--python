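"""Regional and chromosomal association: 1-kb tiles per disjoint region
class (1-Mb windows per chromosome), weighted methylation vs CpG and
non-CpG C>T densities, Spearman correlations per class x stage."""

from common import OUT_DIR, parse_seed, pipeline_config

from methmut import pipeline as pl


def main() -> None:
    cfg = pipeline_config(parse_seed(__doc__))
    regional_corr, _ = pl.run_regional(cfg)
    sperm = regional_corr[(regional_corr["stage"] == "sperm") & (regional_corr["measure"] == "CpG")]
    best = sperm.loc[sperm["spearman_rho"].idxmax()]
    print(f"strongest sperm-stage CpG C>T correlation: {best['region_class']} "
          f"(rho = {best['spearman_rho']:.3f}, {best['n_tiles']} tiles)")
    wins = 0
    pivot = regional_corr[regional_corr["stage"] == "sperm"].pivot(
        index="region_class", columns="measure", values="spearman_rho").dropna()
    wins = int((pivot["CpG"] > pivot["nonCpG"]).sum())
    print(f"CpG rho exceeds non-CpG rho in {wins}/{len(pivot)} region classes (sperm)")
    print(f"tables written to {OUT_DIR / 'regional_correlations.tsv'} "
          f"and chromosome_correlations.tsv")


if __name__ == "__main__":
    main()
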