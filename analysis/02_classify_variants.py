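"""Filter the simulated VCF to rare SNPs (AF < 0.1%, QUAL 100, autosomal,
biallelic) and classify each into the 9 mutation types."""

import json

from common import OUT_DIR, parse_seed, pipeline_config

from methmut import pipeline as pl


def main() -> None:
    cfg = pipeline_config(parse_seed(__doc__))
    report = pl.run_classify(cfg)
    print(f"retained {report['retained']:,} rare SNPs; removed per rule: "
          + json.dumps(report["removed"]))
    cpg_share = sum(v for k, v in report["type_proportions"].items() if k.startswith("CpG"))
    print(f"CpG-context share of classified SNPs: {cpg_share:.3f}")
    print(f"catalog and filter report written to {OUT_DIR}")


if __name__ == "__main__":
    main()
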