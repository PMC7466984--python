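"""Promoter proxies: CpG observed/expected ratio and CpG SNP density per
promoter, correlated with gene expression per tissue. Germline tissues,
whose expression anti-correlates with promoter methylation, should sink
to the bottom of the rho ranking."""

from common import OUT_DIR, parse_seed, pipeline_config

from methmut import pipeline as pl


def main() -> None:
    cfg = pipeline_config(parse_seed(__doc__))
    (density_tab, density_bottom), (oe_tab, _) = pl.run_promoter(cfg)
    print(f"tissues ranked by rho(expression, promoter CpG SNP density): "
          f"{density_bottom}/20 of the lowest 20 are germline")
    # O/E falls with historical methylation, so the germline signal is at
    # the positive end of the rho ranking
    oe_top = int(oe_tab.tail(20)["germline"].sum())
    print(f"tissues ranked by rho(expression, promoter CpG O/E): "
          f"{oe_top}/20 of the highest 20 are germline")
    print(f"tables written to {OUT_DIR / 'expression_vs_cpg_snp_density.tsv'} "
          f"and expression_vs_cpg_oe.tsv")


if __name__ == "__main__":
    main()
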