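"""Genomic interval containers and overlap primitives.

All coordinates are BED-style: 0-based, half-open ``[start, end)``.
Touching intervals (``[10, 20)`` and ``[20, 30)``) do not overlap.
Chromosome names are compared as literal strings; no alias mapping.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

REGION_COLUMNS = ["chrom", "start", "end"]


class RegionSet:
    """A named collection of genomic intervals backed by a DataFrame.

    Parameters
    ----------
    df
        Must contain columns ``chrom``, ``start``, ``end``; any further
        columns (name, score, strand, statistics) are carried along.
    name
        Label for the collection (used in enrichment output).
    """

    def __init__(self, df: pd.DataFrame, name: str = ""):
        missing = [c for c in REGION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"region table lacks columns: {missing}")
        df = df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df["start"] >= df["end"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"invalid interval at row {i}: start "
                f"{df['start'].iat[i]} >= end {df['end'].iat[i]}"
            )
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )
        self.name = name
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RegionSet({self.name!r}, n={len(self)})"

    @classmethod
    def from_records(
        cls, records: Iterable[tuple], name: str = "", columns: list[str] | None = None
    ) -> "RegionSet":
        cols = columns or REGION_COLUMNS
        return cls(pd.DataFrame.from_records(list(records), columns=cols), name=name)

    def _tree_index(self) -> Mapping[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for chrom, sub in self.df.groupby("chrom", sort=False):
                trees[str(chrom)] = IntervalTree.from_tuples(
                    zip(sub["start"].to_numpy(), sub["end"].to_numpy())
                )
            self._trees = trees
        return self._trees

    def overlaps_any(self, other: "RegionSet") -> np.ndarray:
        """Boolean mask over ``self``: does each interval overlap >=1 bp of *other*."""
        trees = other._tree_index()
        chroms = self.df["chrom"].to_numpy()
        starts = self.df["start"].to_numpy()
        ends = self.df["end"].to_numpy()
        out = np.zeros(len(self.df), dtype=bool)
        for i in range(len(self.df)):
            tree = trees.get(str(chroms[i]))
            if tree is not None and tree.overlaps(int(starts[i]), int(ends[i])):
                out[i] = True
        return out

    def count_overlapping(self, other: "RegionSet") -> int:
        return int(self.overlaps_any(other).sum())

    def subset(self, mask: np.ndarray, name: str | None = None) -> "RegionSet":
        return RegionSet(self.df.loc[np.asarray(mask, dtype=bool)], name=name or self.name)

    def keys(self) -> set[tuple]:
        """Identity of each interval as ``(chrom, start, end)`` tuples."""
        return set(
            zip(self.df["chrom"], self.df["start"].astype(int), self.df["end"].astype(int))
        )


def total_span(regions: RegionSet) -> int:
    """Total bp covered, counting overlapping stretches once."""
    covered = 0
    for _, sub in regions.df.groupby("chrom", sort=False):
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        cur_s, cur_e = start[0], end[0]
        for s, e in zip(start[1:], end[1:]):
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    return int(covered)
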