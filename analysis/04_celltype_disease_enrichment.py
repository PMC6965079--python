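#!/usr/bin/env python
"""Cell-type and disease enrichment of the lineage-specific calls.

Summarizes the Fisher enrichment grid (consensus calls vs ASD/AD
deregulated region sets), the oligodendrocyte specificity of hominin
gains, and the three-way log-linear interdependence between gain
status, ASD deregulation and oligodendrocyte specificity.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    run = ROOT / "results" / "run"
    grid = pd.read_csv(run / "enrichment_grid.tsv", sep="\t")
    print("disease enrichment grid (odds ratio vs all atlas regions):")
    print(grid.to_string(index=False))

    ann = pd.read_csv(run / "annotation.tsv", sep="\t")
    cons = pd.read_csv(run / "consensus.tsv", sep="\t")
    gains = set(cons.loc[cons["direction"] == "gain", "region_id"])
    oligo_in_gains = (
        ann.loc[ann["region_id"].isin(gains), "cell_type"] == "oligodendrocyte"
    ).mean()
    oligo_bg = (
        ann.loc[~ann["region_id"].isin(gains), "cell_type"] == "oligodendrocyte"
    ).mean()
    print(f"\noligodendrocyte-specific fraction: gains {oligo_in_gains:.3f} "
          f"vs background {oligo_bg:.3f}")

    llm = pd.read_csv(run / "llm3d.tsv", sep="\t")
    report = json.loads((run / "report.json").read_text())
    print("\nlog-linear model hierarchy (gain x ASD-down x oligodendrocyte):")
    print(llm.to_string(index=False))
    print(f"selected model: {report['llm3d']['selected']}; "
          f"complete-independence p = {report['llm3d']['independence_p']:.3g}")


if __name__ == "__main__":
    main()
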