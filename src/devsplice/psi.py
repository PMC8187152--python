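"""Inclusion/exclusion read counting and length-corrected PSI.

PSI (percentage spliced-in) normalizes inclusion and exclusion read counts
by the number of distinct alignment start positions that can produce each
read type::

    PSI = [i / (ls + lr - 1)] / [i / (ls + lr - 1) + e / (lr - 1)]

with ``ls`` the segment length, ``lr`` the read length, ``i`` the number of
uniquely mapped reads overlapping the segment by >= 1 nt and ``e`` the
number of uniquely mapped junction reads whose intron fully spans the
segment.  PSI is undefined when ``i + e < 10``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .segments import Segment, StructuralInputError

__all__ = [
    "MIN_COVERAGE",
    "PsiValue",
    "ReadAlignment",
    "compute_psi",
    "count_segment_reads",
    "psi_matrix",
    "write_psi_matrix",
]

#: Minimum i + e for PSI to be defined.
MIN_COVERAGE = 10


@dataclass(frozen=True)
class ReadAlignment:
    """Simplified alignment record: sorted genomic blocks plus a uniqueness flag."""

    read_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    unique: bool = True

    def validate(self) -> None:
        prev_end = None
        for s, e in self.blocks:
            if e <= s:
                raise StructuralInputError(f"{self.read_id}: empty block ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise StructuralInputError(f"{self.read_id}: unsorted blocks")
            prev_end = e

    def junction_introns(self) -> list[tuple[int, int]]:
        return [(e0, s1) for (_, e0), (s1, _) in zip(self.blocks, self.blocks[1:])]


@dataclass(frozen=True)
class PsiValue:
    value: Optional[float]
    defined: bool


def count_segment_reads(
    alignments: Iterable[ReadAlignment], segment: Segment
) -> tuple[int, int]:
    """Count inclusion (i) and exclusion (e) reads for one segment.

    Inclusion: uniquely mapped reads with any block overlapping the segment
    interval by at least 1 nt.  Exclusion: uniquely mapped reads carrying a
    junction whose intron fully spans the segment.  Multi-mapped reads are
    ignored entirely.
    """
    i = e = 0
    for aln in alignments:
        if not aln.unique or aln.chrom != segment.chrom:
            continue
        aln.validate()
        if any(s < segment.end and e_ > segment.start for s, e_ in aln.blocks):
            i += 1
        if any(
            s <= segment.start and e_ >= segment.end
            for s, e_ in aln.junction_introns()
        ):
            e += 1
    return i, e


def compute_psi(i: int, e: int, ls: int, lr: int) -> PsiValue:
    """Length-corrected PSI; undefined when total coverage i + e < 10."""
    if i < 0 or e < 0:
        raise ValueError("read counts must be non-negative")
    if ls < 1:
        raise ValueError("segment length must be >= 1")
    if lr < 2:
        raise ValueError("read length must be >= 2")
    if i + e < MIN_COVERAGE:
        return PsiValue(value=None, defined=False)
    inc = i / (ls + lr - 1)
    exc = e / (lr - 1)
    return PsiValue(value=inc / (inc + exc), defined=True)


def psi_matrix(
    counts: pd.DataFrame,
    segment_lengths: dict[str, int] | pd.Series,
    read_length: int | dict[str, int],
) -> pd.DataFrame:
    """Compute a segments x samples PSI matrix from a long counts table.

    Parameters
    ----------
    counts:
        Long-format table with columns segment_id, sample_id, i, e.
    segment_lengths:
        segment_id -> ls.
    read_length:
        Fixed lr, or sample_id -> lr for variable-length libraries.

    Undefined PSI values are NaN.
    """
    lens = pd.Series(segment_lengths)

    def lr_for(sample: str) -> int:
        if isinstance(read_length, dict):
            return read_length[sample]
        return read_length

    df = counts.copy()
    ls = lens.reindex(df["segment_id"]).to_numpy(dtype=float)
    if np.isnan(ls).any():
        missing = sorted(set(df.loc[np.isnan(ls), "segment_id"]))
        raise KeyError(f"segments without length: {missing[:5]}")
    lr = df["sample_id"].map(lr_for).to_numpy(dtype=float)
    i = df["i"].to_numpy(dtype=float)
    e = df["e"].to_numpy(dtype=float)
    inc = i / (ls + lr - 1.0)
    exc = e / (lr - 1.0)
    with np.errstate(invalid="ignore"):
        psi = inc / (inc + exc)
    psi[(i + e) < MIN_COVERAGE] = math.nan
    df["psi"] = psi
    return df.pivot_table(
        index="segment_id", columns="sample_id", values="psi", dropna=False
    )


def write_psi_matrix(matrix: pd.DataFrame, path: str) -> None:
    """Write PSI matrix as TSV with empty cells for undefined values."""
    matrix.to_csv(path, sep="\t", na_rep="", float_format="%.6g")
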