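"""Genomic interval sets with BED-convention coordinates.

Intervals are 0-based, half-open ``[start, end)``.  Canonical form is
per-chromosome sorted and merged; every constructor canonicalizes.  Set
algebra is delegated to :mod:`pyranges`.
"""

from __future__ import annotations

import bisect
from typing import Iterable, Sequence

import pandas as pd
import pyranges as pr

from .variants import chrom_sort_key

__all__ = ["IntervalSet", "read_bed", "write_bed"]


class IntervalSet:
    """An immutable, canonical set of genomic intervals."""

    def __init__(self, intervals: Iterable[Sequence] = ()) -> None:
        rows = [(str(c), int(s), int(e)) for c, s, e in intervals]
        for c, s, e in rows:
            if s < 0 or s >= e:
                raise ValueError(f"invalid interval {c}:{s}-{e}")
        self._intervals: tuple = tuple(self._canonicalize(rows))
        self._by_chrom: dict[str, tuple[list, list]] = {}
        for c, s, e in self._intervals:
            starts, ends = self._by_chrom.setdefault(c, ([], []))
            starts.append(s)
            ends.append(e)

    @staticmethod
    def _canonicalize(rows: list[tuple]) -> list[tuple]:
        if not rows:
            return []
        out: list[tuple] = []
        rows = sorted(rows, key=lambda r: (chrom_sort_key(r[0]), r[1], r[2]))
        cur_c, cur_s, cur_e = rows[0]
        for c, s, e in rows[1:]:
            if c == cur_c and s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((cur_c, cur_s, cur_e))
                cur_c, cur_s, cur_e = c, s, e
        out.append((cur_c, cur_s, cur_e))
        return out

    @classmethod
    def _from_pyranges(cls, gr: pr.PyRanges) -> "IntervalSet":
        df = gr.df
        if df.empty:
            return cls()
        return cls(zip(df.Chromosome.astype(str), df.Start, df.End))

    def _to_pyranges(self) -> pr.PyRanges:
        if not self._intervals:
            return pr.PyRanges(
                pd.DataFrame({"Chromosome": [], "Start": [], "End": []})
            )
        c, s, e = zip(*self._intervals)
        return pr.PyRanges(
            pd.DataFrame({"Chromosome": c, "Start": s, "End": e})
        )

    # -- container protocol -------------------------------------------------
    @property
    def intervals(self) -> tuple:
        return self._intervals

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self):
        return iter(self._intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self._intervals == other._intervals

    def __hash__(self) -> int:
        return hash(self._intervals)

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntervalSet(n={len(self)}, bases={self.total_bases})"

    @property
    def total_bases(self) -> int:
        return sum(e - s for _, s, e in self._intervals)

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a single 0-based position (binary search)."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        i = bisect.bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < ends[i]

    # -- set algebra ---------------------------------------------------------
    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        if not self._intervals or not other._intervals:
            return IntervalSet()
        return self._from_pyranges(self._to_pyranges().set_intersect(other._to_pyranges()))

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self._intervals) + list(other._intervals))

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        if not self._intervals:
            return IntervalSet()
        if not other._intervals:
            return self
        return self._from_pyranges(self._to_pyranges().subtract(other._to_pyranges()))

    def expand(self, flank_bp: int) -> "IntervalSet":
        """Add ``flank_bp`` bases to each side of every interval, then merge.
        Starts are clipped at zero."""
        if flank_bp < 0:
            raise ValueError("flank must be non-negative")
        if flank_bp == 0 or not self._intervals:
            return self
        return IntervalSet(
            (c, max(0, s - flank_bp), e + flank_bp) for c, s, e in self._intervals
        )


def read_bed(path: str) -> IntervalSet:
    """Read a 3+ column BED file (extra columns ignored, headers/comments
    starting with ``#``, ``track`` or ``browser`` skipped)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line with <3 columns: {line!r}")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    return IntervalSet(rows)


def write_bed(intervals: IntervalSet, path: str) -> None:
    with open(path, "w") as fh:
        for c, s, e in intervals:
            fh.write(f"{c}\t{s}\t{e}\n")
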