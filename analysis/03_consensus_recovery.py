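#!/usr/bin/env python
"""Score the hominin consensus calls against the planted truth.

Reads the consensus table produced by 02_run_pipeline.py, compares it
with the truth classes, and reports per-tissue sensitivity and
empirical FDR, plus the per-comparison DE counts behind the calls.
"""

from pathlib import Path

import pandas as pd

from cregatlas.evaluate import match_regions_to_truth, score_consensus_calls
from cregatlas.intervals import GenomicInterval
from cregatlas.simulate import SimulationConfig, make_truth

ROOT = Path(__file__).resolve().parent.parent
SEED = 42


def main() -> None:
    sim = SimulationConfig(seed=SEED)
    truth = make_truth(sim)
    run = ROOT / "results" / "run"
    cons = pd.read_csv(run / "consensus.tsv", sep="\t")
    atlas = pd.read_csv(run / "atlas.tsv", sep="\t")
    regions = [
        GenomicInterval("human", r.human_chrom, r.human_start, r.human_end, id=r.region_id)
        for r in atlas.itertuples(index=False)
    ]
    tested = set(match_regions_to_truth(regions, truth).values())
    rows = []
    for tissue in sim.tissues:
        s = score_consensus_calls(cons[cons["tissue"] == tissue], truth, tested)
        rows.append({"tissue": tissue, **s})
        print(
            f"{tissue}: {int(s['n_called'])} calls / {int(s['n_true'])} planted "
            f"-> sensitivity {s['sensitivity']:.3f}, empirical FDR {s['fdr']:.3f}"
        )
    pd.DataFrame(rows).to_csv(
        ROOT / "results" / "consensus_recovery.tsv", sep="\t", index=False
    )
    gains = cons[cons["direction"] == "gain"].groupby("tissue").size()
    losses = cons[cons["direction"] == "loss"].groupby("tissue").size()
    print(f"\ngains per tissue: {gains.to_dict()}; losses per tissue: {losses.to_dict()}")


if __name__ == "__main__":
    main()
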