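"""4C-seq contact-profile smoothing.

Contact frequency around a viewpoint is smoothed by averaging the
per-fragment-end read counts in running windows of a fixed number of
fragment ends (41 by default) — windows live in fragment-index space,
not genomic distance.  Edge windows are truncated to the available ends
so the output keeps the input length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FragmentProfile", "smooth_fragment_profile"]


@dataclass
class FragmentProfile:
    chrom: str
    viewpoint: int
    positions: np.ndarray  # strictly increasing fragment-end coordinates
    counts: np.ndarray  # non-negative reads per fragment end

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.positions.size != self.counts.size:
            raise ValueError("positions and counts must have equal length")
        if self.positions.size == 0:
            raise ValueError("profile needs at least one fragment end")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("fragment-end coordinates must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return self.positions.size


def smooth_fragment_profile(
    profile: FragmentProfile,
    window: int = 41,
    exclusion_radius: int = 0,
    truncate_edges: bool = True,
) -> np.ndarray:
    """Running-window mean of fragment-end counts.

    The value at index i is the mean of counts over indices
    ``[i-(w-1)/2, i+(w-1)/2]`` clipped to the valid range; with
    ``truncate_edges=False`` positions whose window is truncated get NaN
    instead.  ``exclusion_radius`` masks fragment ends within that many
    bases of the viewpoint before averaging (off by default).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd count of fragment ends")
    counts = profile.counts.copy()
    if exclusion_radius > 0:
        near = np.abs(profile.positions - profile.viewpoint) <= exclusion_radius
        counts[near] = np.nan
    n = counts.size
    half = (window - 1) // 2
    csum = np.concatenate([[0.0], np.nancumsum(counts)])
    cnum = np.concatenate([[0], np.cumsum(~np.isnan(counts))])
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (csum[hi] - csum[lo]) / (cnum[hi] - cnum[lo])
    if not truncate_edges:
        full = (np.arange(n) - half >= 0) & (np.arange(n) + half + 1 <= n)
        out[~full] = np.nan
    return out
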