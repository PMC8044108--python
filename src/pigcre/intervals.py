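"""Genomic interval primitives.

All coordinates are 0-based half-open (`[start, end)`) internally, the BED
convention. Readers of 1-based tables convert at the boundary; writers emit
BED. Interval tables are plain pandas DataFrames with at least the columns
``chrom``, ``start``, ``end`` so that every module shares one currency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

BED_COLUMNS = ["chrom", "start", "end"]


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored half-open span."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp, with validation."""

    def __init__(self, sizes: Mapping[str, int]):
        for name, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
        super().__init__(sizes)

    def validate(self, df: pd.DataFrame) -> None:
        """Raise if any interval in *df* falls outside the genome."""
        for chrom, sub in df.groupby("chrom"):
            if chrom not in self:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if (sub["start"] < 0).any() or (sub["end"] > self[chrom]).any():
                raise ValueError(f"interval outside chromosome {chrom}")

    def total(self) -> int:
        return int(sum(self.values()))


def intervals_frame(records: Iterable[tuple], columns=None) -> pd.DataFrame:
    cols = columns or BED_COLUMNS
    return pd.DataFrame.from_records(list(records), columns=cols)


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge intervals sharing >= 1 bp.

    Half-open convention: bookended intervals (a.end == b.start) share no base
    and are NOT merged.
    """
    if df.empty:
        return df[BED_COLUMNS].copy()
    out = []
    for chrom, sub in sort_intervals(df).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s < cur_e:  # strict: touching does not merge
                cur_e = max(cur_e, int(e))
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append((chrom, cur_s, cur_e))
    return intervals_frame(out)


def center_extend(df: pd.DataFrame, width: int = 2000) -> pd.DataFrame:
    """Replace each interval by the fixed-width window centered at its midpoint."""
    mid = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    half = width // 2
    out = df.copy()
    out["start"] = mid - half
    out["end"] = mid - half + width
    return out.reset_index(drop=True)


def _trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in df.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"].astype(int), sub["end"].astype(int))
        )
    return trees


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it share >= 1 bp with any subject interval?"""
    if query.empty:
        return np.zeros(0, dtype=bool)
    if subject.empty:
        return np.zeros(len(query), dtype=bool)
    trees = _trees(subject)
    hits = np.zeros(len(query), dtype=bool)
    for i, (chrom, s, e) in enumerate(
        zip(query["chrom"], query["start"].astype(int), query["end"].astype(int))
    ):
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps(s, e):
            hits[i] = True
    return hits


def overlap_length(a: GenomicInterval | tuple, b: GenomicInterval | tuple) -> int:
    """Shared bp between two intervals on the same chromosome."""
    if isinstance(a, GenomicInterval):
        a = (a.start, a.end)
    if isinstance(b, GenomicInterval):
        b = (b.start, b.end)
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def read_bed(path, extra_columns: list[str] | None = None) -> pd.DataFrame:
    cols = BED_COLUMNS + (extra_columns or [])
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    return df


def write_bed(df: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    cols = columns or [c for c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)
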