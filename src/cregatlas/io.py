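"""Readers and writers for the on-disk formats the pipeline exchanges.

Plain-text only: BED3/BED6, BEDPE, bedGraph, UCSC chain, and TSV tables
(count matrix, sample sheet).  All readers validate coordinates and
report the offending line number on malformed input; all writers emit
deterministic byte streams so identical runs produce identical files.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from cregatlas.chains import Chain, ChainMap
from cregatlas.intervals import GenomicInterval

__all__ = [
    "ParseError",
    "read_bed",
    "write_bed",
    "read_bed6",
    "write_bed6",
    "read_bedpe",
    "write_bedpe",
    "read_bedgraph",
    "write_bedgraph",
    "read_chain",
    "write_chain",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
]


class ParseError(ValueError):
    """Malformed record in an input file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _lines(path):
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _coords(path, lineno, start_s: str, end_s: str) -> tuple[int, int]:
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
    if start < 0 or end <= start:
        raise ParseError(path, lineno, f"invalid span [{start}, {end})")
    return start, end


def read_bed(path, species: str) -> list[GenomicInterval]:
    """BED3(+name) -> intervals; the optional 4th column becomes the id."""
    out = []
    for lineno, line in _lines(path):
        f = line.split("\t")
        if len(f) < 3:
            raise ParseError(path, lineno, "expected at least 3 BED fields")
        start, end = _coords(path, lineno, f[1], f[2])
        name = f[3] if len(f) > 3 and f[3] != "." else None
        out.append(GenomicInterval(species, f[0], start, end, id=name))
    return out


def write_bed(path, intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for iv in intervals:
            name = iv.id if iv.id is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bed6(path, species: str) -> pd.DataFrame:
    """BED6 -> DataFrame(chrom, start, end, name, score, strand)."""
    rows = []
    for lineno, line in _lines(path):
        f = line.split("\t")
        if len(f) < 6:
            raise ParseError(path, lineno, "expected 6 BED6 fields")
        start, end = _coords(path, lineno, f[1], f[2])
        if f[5] not in "+-.":
            raise ParseError(path, lineno, f"bad strand {f[5]!r}")
        rows.append((f[0], start, end, f[3], float(f[4]), f[5]))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    df.attrs["species"] = species
    return df


def write_bed6(path, df: pd.DataFrame) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t"
                f"{row.score:g}\t{row.strand}\n"
            )


def read_bedpe(path) -> pd.DataFrame:
    """BEDPE -> DataFrame of paired anchors (loop links)."""
    rows = []
    for lineno, line in _lines(path):
        f = line.split("\t")
        if len(f) < 6:
            raise ParseError(path, lineno, "expected at least 6 BEDPE fields")
        s1, e1 = _coords(path, lineno, f[1], f[2])
        s2, e2 = _coords(path, lineno, f[4], f[5])
        name = f[6] if len(f) > 6 else "."
        rows.append((f[0], s1, e1, f[3], s2, e2, name))
    return pd.DataFrame(
        rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name"],
    )


def write_bedpe(path, df: pd.DataFrame) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for row in df.itertuples(index=False):
            name = getattr(row, "name", ".")
            fh.write(
                f"{row.chrom1}\t{row.start1}\t{row.end1}\t"
                f"{row.chrom2}\t{row.start2}\t{row.end2}\t{name}\n"
            )


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    for lineno, line in _lines(path):
        f = line.split("\t")
        if len(f) < 4:
            raise ParseError(path, lineno, "expected 4 bedGraph fields")
        start, end = _coords(path, lineno, f[1], f[2])
        rows.append((f[0], start, end, float(f[3])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(path, df: pd.DataFrame) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.6g}\n")


# ---------------------------------------------------------------------------
# UCSC chain format.  Header:
#   chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id
# followed by "size dt dq" block lines and a bare trailing size.  The tName
# side is read as the source genome and the qName side as the target; for
# qStrand == '-' the query coordinates are converted to forward-strand
# coordinates at the parser boundary.
# ---------------------------------------------------------------------------


def read_chain(path, source_species: str, target_species: str) -> ChainMap:
    chains: list[Chain] = []
    header = None
    src_starts: list[int] = []
    tgt_starts: list[int] = []
    sizes: list[int] = []

    def flush(path, lineno):
        nonlocal header
        if header is None:
            return
        (t_chrom, t_size, t_start, q_chrom, q_size, q_strand, cid) = header
        ss = np.array(src_starts, dtype=np.int64)
        ts = np.array(tgt_starts, dtype=np.int64)
        sz = np.array(sizes, dtype=np.int64)
        if q_strand == "-":
            ts = q_size - (ts + sz)  # forward-strand coordinates of each block
        chains.append(
            Chain(
                src_chrom=t_chrom,
                tgt_chrom=q_chrom,
                src_size=t_size,
                tgt_size=q_size,
                strand=q_strand,
                src_starts=ss,
                tgt_starts=ts,
                sizes=sz,
                chain_id=cid,
            )
        )
        header = None
        src_starts.clear()
        tgt_starts.clear()
        sizes.clear()

    in_blocks = False
    spos = tpos = 0
    for lineno, line in _lines(path):
        f = line.split()
        if f[0] == "chain":
            flush(path, lineno)
            if len(f) < 13:
                raise ParseError(path, lineno, "short chain header")
            if f[4] != "+":
                raise ParseError(path, lineno, "tStrand must be '+'")
            header = (f[2], int(f[3]), int(f[5]), f[7], int(f[8]), f[9], int(f[12]))
            spos, tpos = int(f[5]), int(f[10])
            in_blocks = True
        elif in_blocks:
            if header is None:
                raise ParseError(path, lineno, "block line outside a chain record")
            try:
                nums = [int(x) for x in f]
            except ValueError:
                raise ParseError(path, lineno, "non-integer block line")
            size = nums[0]
            src_starts.append(spos)
            tgt_starts.append(tpos)
            sizes.append(size)
            if len(nums) == 3:
                spos += size + nums[1]
                tpos += size + nums[2]
            elif len(nums) == 1:
                flush(path, lineno)
                in_blocks = False
            else:
                raise ParseError(path, lineno, "block line must have 1 or 3 fields")
    flush(path, 0)
    return ChainMap(source_species, target_species, chains)


def write_chain(path, chainmap: ChainMap) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for ch in chainmap.chains:
            if len(ch.sizes) == 0:
                continue
            ss, ts, sz = ch.src_starts, ch.tgt_starts, ch.sizes
            t_start, t_end = int(ss[0]), int(ss[-1] + sz[-1])
            if ch.strand == "+":
                q0, q1 = int(ts[0]), int(ts[-1] + sz[-1])
                qs = ts
            else:
                # emit reverse-strand coordinates as the format requires
                qs = ch.tgt_size - (ts + sz)
                order = np.argsort(ss)
                qs = qs[order]
                q0, q1 = int(qs[0]), int(qs[-1] + sz[order][-1])
            fh.write(
                f"chain 1000 {ch.src_chrom} {ch.src_size} + {t_start} {t_end} "
                f"{ch.tgt_chrom} {ch.tgt_size} {ch.strand} {q0} {q1} {ch.chain_id}\n"
            )
            for k in range(len(sz) - 1):
                dt = int(ss[k + 1] - (ss[k] + sz[k]))
                dq = int(qs[k + 1] - (qs[k] + sz[k]))
                fh.write(f"{int(sz[k])}\t{dt}\t{dq}\n")
            fh.write(f"{int(sz[-1])}\n\n")


def read_counts(path) -> pd.DataFrame:
    """Counts TSV (region_id + one integer column per sample) -> DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ParseError(path, 0, "duplicate region ids")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or np.any(arr < 0):
        raise ParseError(path, 0, "counts must be non-negative numbers")
    if np.any(arr != np.floor(arr)):
        raise ParseError(path, 0, "counts must be integral")
    return df.astype(np.int64)


def write_counts(path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="region_id", lineterminator="\n")


SAMPLE_COLUMNS = ["sample_id", "species", "tissue", "replicate", "batch", "library_size"]


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"sample sheet missing columns {missing}")
    if df["sample_id"].duplicated().any():
        raise ParseError(path, 0, "duplicate sample ids")
    return df


def write_sample_sheet(path, sheet: pd.DataFrame) -> None:
    sheet.to_csv(path, sep="\t", index=False, lineterminator="\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    return p
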