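"""Genomic interval model shared by every stage of the pipeline.

All coordinates are 0-based half-open throughout the package; conversions
from 1-based formats (RepeatMasker) happen at the I/O boundary only.
Overlap logic is strand-blind: strand is carried as an annotation and only
the motif scanner interprets it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = ["GenomeInterval", "RegionSet"]


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A half-open span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomeInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


_COLUMNS = ["chrom", "start", "end", "id", "score", "strand"]


class RegionSet:
    """An ordered collection of intervals with optional per-interval id/score.

    Internally a pandas DataFrame with BED6-like columns. Interval-algebra
    primitives (merge, union bp, per-query coverage) operate on per-chromosome
    sorted numpy arrays and are cross-checked against a per-base bitmap oracle
    in the test suite.
    """

    def __init__(self, df: pd.DataFrame | None = None, name: str = ""):
        if df is None:
            df = pd.DataFrame(columns=_COLUMNS)
        df = df.copy()
        for col, default in (("id", "."), ("score", 0.0), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[_COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and not (df["start"] < df["end"]).all():
            bad = df.index[~(df["start"] < df["end"])][0]
            raise ValueError(f"interval with start >= end at row {bad}")
        if len(df) and (df["start"] < 0).any():
            raise ValueError("negative start coordinate")
        self.df = df.reset_index(drop=True)
        self.name = name

    # -- construction ------------------------------------------------------

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomeInterval], name: str = ""
    ) -> "RegionSet":
        rows = [
            (iv.chrom, iv.start, iv.end, ".", 0.0, iv.strand) for iv in intervals
        ]
        return cls(pd.DataFrame(rows, columns=_COLUMNS), name=name)

    @classmethod
    def from_arrays(
        cls,
        chroms,
        starts,
        ends,
        ids=None,
        scores=None,
        strands=None,
        name: str = "",
    ) -> "RegionSet":
        df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
        if ids is not None:
            df["id"] = ids
        if scores is not None:
            df["score"] = scores
        if strands is not None:
            df["strand"] = strands
        return cls(df, name=name)

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomeInterval]:
        for row in self.df.itertuples(index=False):
            yield GenomeInterval(row.chrom, int(row.start), int(row.end), row.strand)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        a = self.sort().df
        b = other.sort().df
        return a.equals(b)

    def __repr__(self) -> str:
        return f"RegionSet(name={self.name!r}, n={len(self)})"

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def sort(self) -> "RegionSet":
        out = RegionSet(
            self.df.sort_values(["chrom", "start", "end"], kind="mergesort"),
            name=self.name,
        )
        return out

    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    # -- interval algebra --------------------------------------------------

    def _per_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for chrom, sub in self.df.groupby("chrom", sort=True):
            order = np.lexsort((sub["end"].to_numpy(), sub["start"].to_numpy()))
            out[chrom] = (
                sub["start"].to_numpy()[order],
                sub["end"].to_numpy()[order],
            )
        return out

    def is_merged(self) -> bool:
        """True iff intervals are disjoint, non-abutting-agnostic and sorted."""
        for starts, ends in self._per_chrom().values():
            if len(starts) > 1 and not (starts[1:] >= ends[:-1]).all():
                return False
        return True

    def merge(self) -> "RegionSet":
        """Union of intervals: non-overlapping, sorted; abutting runs join."""
        rows = []
        for chrom, (starts, ends) in self._per_chrom().items():
            ms, me = _merge_arrays(starts, ends)
            rows.extend((chrom, s, e) for s, e in zip(ms, me))
        return RegionSet(
            pd.DataFrame(rows, columns=["chrom", "start", "end"]), name=self.name
        )

    def coverage_of(
        self, chroms, starts, ends, require_merged: bool = True
    ) -> np.ndarray:
        """bp of each query interval covered by this (merged) set."""
        if require_merged and not self.is_merged():
            raise ValueError("RegionSet must be merged (non-overlapping) first")
        per = self._per_chrom()
        chroms = np.asarray(chroms)
        qs = np.asarray(starts, dtype=np.int64)
        qe = np.asarray(ends, dtype=np.int64)
        out = np.zeros(len(qs), dtype=np.int64)
        for chrom in np.unique(chroms):
            mask = chroms == chrom
            if chrom not in per:
                continue
            s, e = per[chrom]
            out[mask] = _covered_bp(s, e, qs[mask], qe[mask])
        return out

    def coverage_fraction(self, region: GenomeInterval) -> float:
        """Fraction of ``region`` covered by this merged set."""
        if region.length == 0:
            raise ValueError("zero-length region")
        bp = self.coverage_of([region.chrom], [region.start], [region.end])[0]
        return bp / region.length

    def contains_interval(self, region: GenomeInterval) -> bool:
        """True iff every base of ``region`` lies in the union of this set."""
        merged = self if self.is_merged() else self.merge()
        bp = merged.coverage_of([region.chrom], [region.start], [region.end])[0]
        return int(bp) == region.length

    def complement(self, chrom_sizes: Mapping[str, int]) -> "RegionSet":
        """Gaps of this set relative to whole chromosomes."""
        merged = self.merge()
        per = merged._per_chrom()
        rows = []
        for chrom, size in chrom_sizes.items():
            s, e = per.get(chrom, (np.array([], dtype=np.int64),) * 2)
            edges_s = np.concatenate([[0], e])
            edges_e = np.concatenate([s, [size]])
            for a, b in zip(edges_s, edges_e):
                if b > a:
                    rows.append((chrom, int(a), int(b)))
        return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def union(self, other: "RegionSet") -> "RegionSet":
        df = pd.concat([self.df, other.df], ignore_index=True)
        return RegionSet(df).merge()

    def subset(self, mask) -> "RegionSet":
        return RegionSet(self.df[np.asarray(mask)], name=self.name)

    def intervals(self) -> list[GenomeInterval]:
        return list(self)


def _merge_arrays(starts: np.ndarray, ends: np.ndarray):
    """Merge interval arrays sorted by start; abutting intervals join."""
    if len(starts) == 0:
        return starts.astype(np.int64), ends.astype(np.int64)
    run_end = np.maximum.accumulate(ends)
    new_block = np.concatenate([[True], starts[1:] > run_end[:-1]])
    last = np.concatenate([np.flatnonzero(new_block)[1:] - 1, [len(starts) - 1]])
    return starts[new_block].astype(np.int64), run_end[last].astype(np.int64)


def _covered_bp(
    starts: np.ndarray, ends: np.ndarray, qs: np.ndarray, qe: np.ndarray
) -> np.ndarray:
    """Vectorized covered-bp of queries against merged blocks on one chrom."""
    prefix = np.concatenate([[0], np.cumsum(ends - starts)])
    lo = np.searchsorted(ends, qs, side="right")
    hi = np.searchsorted(starts, qe, side="left")
    total = prefix[hi] - prefix[lo]
    has = hi > lo
    left_trim = np.zeros_like(total)
    right_trim = np.zeros_like(total)
    left_trim[has] = np.maximum(0, qs[has] - starts[lo[has]])
    right_trim[has] = np.maximum(0, ends[hi[has] - 1] - qe[has])
    return total - left_trim - right_trim
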