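#!/usr/bin/env python
"""Assessment-table comparison of assembly strategies on one shared truth.

Runs the full pipeline (simulate -> reference -> evidence -> call -> filter
-> heterozygosity -> screens) for the redundant, clustered and
supertranscript strategies over a truth with 30% of genes in 2%-divergent
paralog families, and prints the per-group H_o/H_E panel with ratios. The
clustered strategy collapses these families, so its haploid H_o is inflated
by paralog mapping; the redundant strategy splits alleles and loses callable
coverage. Writes results/strategy_summary.tsv and results/report.json.
"""

import json
from pathlib import Path

from haplopsc.config import PipelineConfig, SimConfig
from haplopsc.pipeline import run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = PipelineConfig(
        sim=SimConfig(n_genes=100, seed=1, paralog_fraction=0.3,
                      paralog_divergence=0.02),
        strategies=("redundant", "clustered", "supertranscript"))
    rep = run_pipeline(cfg)
    df = rep.summary_frame()
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "strategy_summary.tsv", sep="\t", index=False)
    (OUT / "report.json").write_text(rep.to_json())
    print(df.to_string(index=False))
    for name, res in rep.strategies.items():
        r = res.summary.ratios
        fmt = {k: ("NA" if v is None else f"{v:.2f}") for k, v in r.items()}
        print(f"{name}: Ho(ME)/Ho(EM)={fmt['Ho_ME/EM']} "
              f"Ho/He: ME={fmt['HoHe_ME']} EM={fmt['HoHe_EM']} "
              f"VEG={fmt['HoHe_VEG']}")
    print(json.dumps(rep.truth_eval, indent=2))


if __name__ == "__main__":
    main()
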