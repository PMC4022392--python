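"""Callable-loci computation and coverage summaries.

A base is confidently callable when it has at least 20-fold read depth and
at most 10% of its reads are ambiguously mapped (mapping quality zero).
Coverage enters as a per-base TSV track (chrom, 1-based pos, depth, MAPQ0
read count); bases absent from the track have zero depth and are therefore
never callable.  Depth-threshold summaries are computed over the un-flanked
target intervals, while the callable fraction of coding exons uses targets
expanded by a flank (variants are called in the flanks too).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet

__all__ = [
    "DEFAULT_MIN_DEPTH",
    "DEFAULT_MAX_MAPQ0_FRAC",
    "CoverageTrack",
    "CoverageSummary",
    "callable_regions",
    "coverage_summary",
    "squared_off_callable",
]

DEFAULT_MIN_DEPTH = 20
DEFAULT_MAX_MAPQ0_FRAC = 0.10


class CoverageTrack:
    """Per-base depth and MAPQ0 counts, keyed by (chrom, 1-based pos)."""

    COLUMNS = ["chrom", "pos", "depth", "mapq0"]

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"coverage track missing columns {missing}")
        df = df[self.COLUMNS].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["depth"] = df["depth"].astype(np.int64)
        df["mapq0"] = df["mapq0"].astype(np.int64)
        if (df.depth < 0).any():
            raise ValueError("negative depth")
        if (df.mapq0 > df.depth).any():
            raise ValueError("mapq0 count exceeds depth")
        self.df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )

    @classmethod
    def from_tsv(cls, path: str) -> "CoverageTrack":
        """Read a ``chrom  pos  depth  mapq0`` TSV (gzip accepted)."""
        df = pd.read_csv(
            path,
            sep="\t",
            names=cls.COLUMNS,
            header=0 if _has_header(path) else None,
            comment="#",
        )
        return cls(df)

    def to_tsv(self, path: str) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def callable_mask(
        self,
        min_depth: int = DEFAULT_MIN_DEPTH,
        max_mapq0_frac: float = DEFAULT_MAX_MAPQ0_FRAC,
    ) -> pd.DataFrame:
        """The track rows satisfying the callable predicate."""
        d = self.df
        ok = (d.depth >= min_depth) & (d.mapq0 <= max_mapq0_frac * d.depth)
        return d[ok]

    def depth_over(self, intervals: IntervalSet) -> np.ndarray:
        """Per-base depth across every base of ``intervals`` (absent = 0)."""
        lookup = {
            (c, p): dep
            for c, p, dep in zip(self.df.chrom, self.df.pos, self.df.depth)
        }
        out = np.empty(intervals.total_bases, dtype=np.int64)
        i = 0
        for chrom, start, end in intervals:
            for pos0 in range(start, end):
                out[i] = lookup.get((chrom, pos0 + 1), 0)
                i += 1
        return out


def _has_header(path: str) -> bool:
    opener = pd.io.common.get_handle(path, "r")
    with opener as h:
        first = h.handle.readline()
    fields = first.rstrip("\n").split("\t")
    return len(fields) >= 4 and not fields[1].isdigit()


@dataclass
class CoverageSummary:
    """Target coverage statistics in the layout of a per-replicate row."""

    mean_depth: float
    pct_ge_1x: float
    pct_ge_10x: float
    pct_ge_20x: float
    pct_ge_30x: float
    pct_callable_coding: Optional[float]

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _runs_to_intervals(mask_df: pd.DataFrame) -> IntervalSet:
    """Maximal runs of consecutive positions → half-open intervals."""
    if mask_df.empty:
        return IntervalSet()
    chrom = mask_df.chrom.to_numpy()
    pos = mask_df.pos.to_numpy()
    breaks = np.flatnonzero((chrom[1:] != chrom[:-1]) | (pos[1:] != pos[:-1] + 1))
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(pos) - 1]))
    return IntervalSet(
        (chrom[i], pos[i] - 1, pos[j]) for i, j in zip(starts, ends)
    )


def callable_regions(
    track: CoverageTrack,
    intervals: Optional[IntervalSet] = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_mapq0_frac: float = DEFAULT_MAX_MAPQ0_FRAC,
) -> IntervalSet:
    """Maximal runs of callable bases, intersected with target intervals.

    A base is callable iff ``depth >= min_depth`` and
    ``mapq0/depth <= max_mapq0_frac``; both boundaries are inclusive
    ("a minimum of" 20-fold, "no more than" 10% MAPQ0).
    """
    if min_depth <= 0 or max_mapq0_frac < 0:
        raise ValueError("thresholds must be positive")
    regions = _runs_to_intervals(track.callable_mask(min_depth, max_mapq0_frac))
    if intervals is not None:
        regions = regions.intersect(intervals)
    return regions


def coverage_summary(
    track: CoverageTrack,
    stat_intervals: IntervalSet,
    coding_intervals: Optional[IntervalSet] = None,
    flank_bp: int = 100,
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_mapq0_frac: float = DEFAULT_MAX_MAPQ0_FRAC,
) -> CoverageSummary:
    """Mean depth and threshold fractions over the un-flanked targets, plus
    the callable percentage of coding exons computed over flanked targets.

    The mean includes zero-depth target bases.  Percentages are returned at
    full precision; round to one decimal for tabular display.
    """
    if stat_intervals.total_bases == 0:
        raise ValueError("empty stat intervals")
    depth = track.depth_over(stat_intervals)
    n = depth.size
    pct = lambda t: 100.0 * float((depth >= t).sum()) / n  # noqa: E731

    pct_coding = None
    if coding_intervals is not None:
        if coding_intervals.total_bases == 0:
            raise ValueError("empty coding intervals")
        callable_set = callable_regions(
            track,
            stat_intervals.expand(flank_bp),
            min_depth,
            max_mapq0_frac,
        )
        pct_coding = (
            100.0
            * callable_set.intersect(coding_intervals).total_bases
            / coding_intervals.total_bases
        )

    return CoverageSummary(
        mean_depth=float(depth.mean()),
        pct_ge_1x=pct(1),
        pct_ge_10x=pct(10),
        pct_ge_20x=pct(20),
        pct_ge_30x=pct(30),
        pct_callable_coding=pct_coding,
    )


def squared_off_callable(
    tracks: Sequence[CoverageTrack],
    intervals: Optional[IntervalSet] = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_mapq0_frac: float = DEFAULT_MAX_MAPQ0_FRAC,
) -> IntervalSet:
    """The "squared-off" intersection of callable regions across replicates:
    a base survives only if every replicate can call it."""
    if len(tracks) < 2:
        raise ValueError("need at least two replicate tracks")
    sets = [
        callable_regions(t, intervals, min_depth, max_mapq0_frac) for t in tracks
    ]
    return reduce(lambda a, b: a.intersect(b), sets)
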