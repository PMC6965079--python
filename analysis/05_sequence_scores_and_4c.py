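#!/usr/bin/env python
"""Sequence-level signatures of the hominin-specific calls, plus 4C.

Compares hominin nucleotide-change percentages and masked conservation
between called gains and stable atlas regions (the planted directions:
more hominin-branch changes and lower conservation at gains), and
summarizes the smoothed 4C contact profile.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cregatlas.seqscores import compare_score_distributions

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    run = ROOT / "results" / "run"
    scores = pd.read_csv(run / "scores.tsv", sep="\t")
    cons = pd.read_csv(run / "consensus.tsv", sep="\t")
    gains = set(cons.loc[cons["direction"] == "gain", "region_id"])
    changed = set(cons["region_id"])
    g = scores[scores["region_id"].isin(gains)]
    s = scores[~scores["region_id"].isin(changed)]
    for col, label in [
        ("pct_hominin_change", "hominin nucleotide changes (%)"),
        ("mean_conservation", "masked conservation"),
    ]:
        a, b = g[col].dropna().to_numpy(), s[col].dropna().to_numpy()
        t, p = compare_score_distributions(a, b)
        print(f"{label}: gains {a.mean():.3f} vs stable {b.mean():.3f} "
              f"(Welch t = {t:.2f}, p = {p:.3g})")

    fourc = pd.read_csv(
        run / "fourc_smoothed.bedgraph", sep="\t",
        names=["chrom", "start", "end", "value"],
    )
    report = json.loads((run / "report.json").read_text())
    print(f"\n4C: {report['fourc']['n_fragment_ends']} fragment ends smoothed "
          f"in windows of {report['fourc']['window']}; "
          f"peak smoothed coverage {fourc['value'].max():.1f}, "
          f"median {fourc['value'].median():.2f}")


if __name__ == "__main__":
    main()
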