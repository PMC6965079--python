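"""Scoring pipeline output against the planted truth of a synthetic bundle."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from cregatlas.atlas import GREAtlas
from cregatlas.intervals import GenomicInterval, overlap_query

__all__ = [
    "match_regions_to_truth",
    "score_discard_ledger",
    "score_consensus_calls",
]


def _truth_intervals(truth: pd.DataFrame, reference: str) -> list[GenomicInterval]:
    return [
        GenomicInterval(reference, row.chrom, row.start, row.end, id=row.region_id)
        for row in truth.itertuples(index=False)
    ]


def match_regions_to_truth(
    regions: list[GenomicInterval], truth: pd.DataFrame, reference: str = "human"
) -> dict[str, str]:
    """Map each region id to the overlapping truth region (max overlap wins)."""
    tivs = {iv.id: iv for iv in _truth_intervals(truth, reference)}
    by_id = {iv.id: iv for iv in regions}
    best: dict[str, tuple[int, str]] = {}
    for rid, tid in overlap_query(regions, list(tivs.values())):
        ov = by_id[rid].overlap(tivs[tid])
        if rid not in best or ov > best[rid][0]:
            best[rid] = (ov, tid)
    return {rid: tid for rid, (_, tid) in best.items()}


def score_discard_ledger(
    ledger: pd.DataFrame,
    truth: pd.DataFrame,
    reference: str = "human",
    reasons: Mapping[str, tuple[str, ...]] = {
        "unmappable": ("unmappable", "multi_mapped", "size_violation"),
        "repeat_confounded": ("repeat",),
    },
) -> pd.DataFrame:
    """Precision/recall of the discard ledger against planted classes.

    For each planted class, the predicted set is the ledger rows whose
    reason belongs to that class (matched to truth regions by maximum
    overlap) and the truth set is the regions planted with that class.
    """
    regions = [
        GenomicInterval(reference, row.chrom, row.start, row.end, id=row.region_id)
        for row in ledger.itertuples(index=False)
    ]
    link = match_regions_to_truth(regions, truth, reference)
    rows = []
    for true_class, ledger_reasons in reasons.items():
        planted = set(truth.loc[truth["true_class"] == true_class, "region_id"])
        predicted = {
            link[row.region_id]
            for row in ledger.itertuples(index=False)
            if row.reason in ledger_reasons and row.region_id in link
        }
        tp = len(planted & predicted)
        precision = tp / len(predicted) if predicted else float("nan")
        recall = tp / len(planted) if planted else float("nan")
        rows.append(
            {
                "true_class": true_class,
                "n_planted": len(planted),
                "n_predicted": len(predicted),
                "tp": tp,
                "precision": precision,
                "recall": recall,
            }
        )
    return pd.DataFrame(rows)


def score_consensus_calls(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    tested_ids: set[str],
    lineage: str = "hominin",
) -> dict[str, float]:
    """Sensitivity and empirical FDR of lineage calls against the truth.

    ``calls['region_id']`` must be truth region ids (or linked to them
    beforehand); ``tested_ids`` restricts the truth to regions that
    actually entered the test (e.g. survived the atlas).
    """
    class_of = dict(zip(truth["region_id"], truth["true_class"]))
    want = {"hominin": ("hominin_gain", "hominin_loss")}.get(
        lineage, (f"{lineage}_gain", f"{lineage}_loss")
    )
    truth_gain = {r for r in tested_ids if class_of.get(r) == want[0]}
    truth_loss = {r for r in tested_ids if class_of.get(r) == want[1]}
    called_gain = set(calls.loc[calls["direction"] == "gain", "region_id"])
    called_loss = set(calls.loc[calls["direction"] == "loss", "region_id"])
    tp = len(called_gain & truth_gain) + len(called_loss & truth_loss)
    n_called = len(called_gain) + len(called_loss)
    n_true = len(truth_gain) + len(truth_loss)
    return {
        "sensitivity": tp / n_true if n_true else float("nan"),
        "fdr": (n_called - tp) / n_called if n_called else 0.0,
        "n_called": float(n_called),
        "n_true": float(n_true),
    }
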