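"""Sequence-level scores: conservation and hominin nucleotide changes.

The hominin nucleotide-change percentage of a region counts, among the
validly aligned columns of a four-species alignment, those where human
and chimpanzee share a base that differs from the macaque base and from
the marmoset base — the signature of a substitution on the hominin
branch.  Conservation is the mean of a phastCons-style per-base track
over the open-chromatin-masked bases of the region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cregatlas.intervals import GenomicInterval

__all__ = [
    "AlignmentColumns",
    "hominin_nucleotide_change_pct",
    "mean_conservation_masked",
    "compare_score_distributions",
]


@dataclass
class AlignmentColumns:
    """Aligned base columns for one region across the four species.

    ``bases`` maps species label -> equal-length uppercase strings; the
    boolean ``valid`` mask marks columns aligned and non-gap in all four
    species.  A missing mask means every column is valid.
    """

    region_id: str
    bases: dict[str, str]
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.bases.values()}
        if len(lengths) != 1:
            raise ValueError("aligned strings must have equal length")
        n = lengths.pop()
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.size != n:
                raise ValueError("mask length does not match alignment length")


def hominin_nucleotide_change_pct(
    cols: AlignmentColumns,
    require_monkey_agreement: bool = False,
    species: tuple[str, str, str, str] = ("human", "chimp", "macaque", "marmoset"),
) -> float | None:
    """Percentage of valid columns carrying a hominin-branch change.

    A column qualifies when human == chimpanzee while differing from the
    macaque base and from the marmoset base (the two monkey bases need
    not agree unless ``require_monkey_agreement``).  Returns ``None``
    when no valid column exists.
    """
    hu, ch, rm, mm = (
        np.frombuffer(cols.bases[s].encode("ascii"), dtype="S1") for s in species
    )
    valid = cols.valid
    gap = (hu == b"-") | (ch == b"-") | (rm == b"-") | (mm == b"-")
    valid = valid & ~gap
    n_valid = int(valid.sum())
    if n_valid == 0:
        return None
    qual = (hu == ch) & (hu != rm) & (hu != mm)
    if require_monkey_agreement:
        qual &= rm == mm
    return 100.0 * int((qual & valid).sum()) / n_valid


def mean_conservation_masked(
    region: GenomicInterval,
    track: pd.DataFrame,
    mask: list[GenomicInterval],
) -> float | None:
    """Mean per-base conservation over region ∩ mask.

    ``track`` is a bedGraph-style frame (chrom, start, end, value) with
    scores in [0, 1].  Returns ``None`` when the masked intersection
    carries no scored base.
    """
    mask_spans = sorted(
        (max(region.start, m.start), min(region.end, m.end))
        for m in mask
        if m.chrom == region.chrom and m.start < region.end and m.end > region.start
    )
    if not mask_spans:
        return None
    seg = track[
        (track["chrom"] == region.chrom)
        & (track["start"] < region.end)
        & (track["end"] > region.start)
    ]
    total = 0.0
    bases = 0
    for row in seg.itertuples(index=False):
        for ms, me in mask_spans:
            lo, hi = max(row.start, ms), min(row.end, me)
            if lo < hi:
                total += row.value * (hi - lo)
                bases += hi - lo
    if bases == 0:
        return None
    return total / bases


def compare_score_distributions(
    group_a: np.ndarray, group_b: np.ndarray
) -> tuple[float, float]:
    """Welch two-sample t test between two score vectors.

    Returns ``(t, p)``; two degenerate identical zero-variance groups
    short-circuit to ``(0, 1)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
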