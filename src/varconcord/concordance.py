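"""Genotype-concordance metrics between a truth and a test callset.

Two callsets are joined on strict variant equality inside a set of target
intervals, producing a truth×test count matrix over the genotype classes
{HOMREF, HET, HOMALT, NOCALL, ABSENT}.  Calls flagged by the variant filter
are treated as no-calls; a variant key present in only one callset lands in
the other side's ABSENT class.  All four metrics derive from this matrix:

concordance
    matching genotypes among sites genotyped in both callsets,
NRS (non-reference sensitivity)
    truth non-reference sites at which the test calls the same variant
    non-reference (any zygosity),
NRC (non-reference genotype concordance)
    genotype-aware recall: truth non-reference genotypes matched exactly,
precision
    test non-reference genotype calls matched exactly by the truth.

Concordance is symmetric under exchanging truth and test; the other three
are not, and replicate comparisons are therefore run in both directions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .variants import Callset, FilterStatus, GenotypeClass

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSES",
    "ConcordanceMatrix",
    "ConcordanceReport",
    "join_callsets",
    "metrics",
    "compare",
    "pairwise_replicates",
]

#: Matrix axis order.  ABSENT marks keys missing from that side entirely.
CLASSES = ["HOMREF", "HET", "HOMALT", "NOCALL", "ABSENT"]
_GENOTYPED = ["HOMREF", "HET", "HOMALT"]
_NONREF = ["HET", "HOMALT"]


@dataclass
class ConcordanceMatrix:
    """Truth×test genotype count table for one joined callset pair."""

    counts: pd.DataFrame  # index=truth class, columns=test class
    truth_id: str
    test_id: str
    interval_bases: int
    truth_exhaustive: bool = False

    def __post_init__(self) -> None:
        assert list(self.counts.index) == CLASSES
        assert list(self.counts.columns) == CLASSES
        if self.counts.loc["ABSENT", "ABSENT"] != 0:
            raise ValueError("(ABSENT, ABSENT) cell must be structurally zero")
        if (self.counts.values < 0).any():
            raise ValueError("negative cell count")

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())


@dataclass
class ConcordanceReport:
    """The four concordance metrics plus their supporting counts.

    A metric whose denominator is empty is ``None`` (absent), never 0 or 1.
    """

    truth_id: str
    test_id: str
    concordance: Optional[float]
    nrs: Optional[float]
    nrc: Optional[float]
    precision: Optional[float]
    n_joint: int
    n_truth_nonref: int
    n_test_nonref: int
    n_test_only_nonref: int = 0

    def as_dict(self) -> dict:
        return {
            "truth_id": self.truth_id,
            "test_id": self.test_id,
            "concordance": self.concordance,
            "nrs": self.nrs,
            "nrc": self.nrc,
            "precision": self.precision,
            "n_joint": self.n_joint,
            "n_truth_nonref": self.n_truth_nonref,
            "n_test_nonref": self.n_test_nonref,
            "n_test_only_nonref": self.n_test_only_nonref,
        }


def _effective_class(callset: Callset, key: tuple) -> str:
    call = callset._calls.get(key)
    if call is None:
        return "ABSENT"
    if call.filter_status is FilterStatus.FILTERED:
        return "NOCALL"
    return call.gclass.value


def join_callsets(
    truth: Callset,
    test: Callset,
    intervals: Optional[IntervalSet] = None,
) -> ConcordanceMatrix:
    """Join two normalized callsets on strict variant equality.

    Every distinct variant key present in either callset (within the
    intervals, when given) contributes to exactly one cell.
    """
    if intervals is not None:
        truth = truth.restrict(intervals)
        test = test.restrict(intervals)
    idx = {name: i for i, name in enumerate(CLASSES)}
    grid = np.zeros((len(CLASSES), len(CLASSES)), dtype=int)
    for key in truth.keys() | test.keys():
        grid[idx[_effective_class(truth, key)], idx[_effective_class(test, key)]] += 1
    return ConcordanceMatrix(
        pd.DataFrame(grid, index=CLASSES, columns=CLASSES),
        truth.replicate_id,
        test.replicate_id,
        interval_bases=intervals.total_bases if intervals is not None else 0,
        truth_exhaustive=truth.exhaustive,
    )


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(
    matrix: ConcordanceMatrix, truth_exhaustive: Optional[bool] = None
) -> ConcordanceReport:
    """Compute concordance, NRS, NRC and precision from a joined matrix.

    ``truth_exhaustive`` controls whether test calls at keys the truth set
    does not carry count against precision: an exhaustive truth set (array,
    validated panel, high-confidence reference) reports every variant in its
    intervals, so a test-only non-reference call is a false positive; against
    a non-exhaustive truth those calls are excluded from the precision
    denominator and reported separately.  Defaults to the flag stored on the
    matrix's truth callset.
    """
    if truth_exhaustive is None:
        truth_exhaustive = matrix.truth_exhaustive
    c = matrix.counts
    diag_g = sum(c.loc[g, g] for g in _GENOTYPED)
    n_joint = int(c.loc[_GENOTYPED, _GENOTYPED].values.sum())
    concordance = _ratio(diag_g, n_joint)

    truth_nonref_total = int(c.loc[_NONREF, :].values.sum())
    nrs = _ratio(int(c.loc[_NONREF, _NONREF].values.sum()), truth_nonref_total)
    diag_nr = sum(c.loc[g, g] for g in _NONREF)
    nrc = _ratio(diag_nr, truth_nonref_total)

    test_nonref_total = int(c.loc[:, _NONREF].values.sum())
    test_only_nonref = int(c.loc["ABSENT", _NONREF].values.sum())
    if truth_exhaustive:
        precision = _ratio(diag_nr, test_nonref_total)
    else:
        precision = _ratio(diag_nr, test_nonref_total - test_only_nonref)

    return ConcordanceReport(
        truth_id=matrix.truth_id,
        test_id=matrix.test_id,
        concordance=concordance,
        nrs=nrs,
        nrc=nrc,
        precision=precision,
        n_joint=n_joint,
        n_truth_nonref=truth_nonref_total,
        n_test_nonref=test_nonref_total,
        n_test_only_nonref=test_only_nonref,
    )


def compare(
    truth: Callset,
    test: Callset,
    intervals: Optional[IntervalSet] = None,
    truth_exhaustive: Optional[bool] = None,
) -> ConcordanceReport:
    """Join and score in one step."""
    return metrics(join_callsets(truth, test, intervals), truth_exhaustive)


def pairwise_replicates(
    callsets: Sequence[Callset],
    intervals: Optional[IntervalSet] = None,
    design: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Concordance reports for every unordered pair of same-sample replicates.

    There is no truth callset between technical replicates, so each pair is
    scored twice with the roles swapped; the two directions share one joined
    matrix, which makes the symmetric concordance identical by construction
    and exposes the NRS/NRC/precision asymmetries.  Pairs with mismatched
    sample names are skipped with a warning.  When a replicate-design table
    is given, each row also carries the pair's comparison-kind labels.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two callsets")
    kinds_lookup: dict[frozenset, str] = {}
    if design is not None:
        from .replicates import build_design

        for pa, pb, ks, _label in build_design(design).pairs:
            kinds_lookup[frozenset((pa, pb))] = ",".join(sorted(ks))

    rows = []
    for i in range(len(callsets)):
        for j in range(i + 1, len(callsets)):
            a, b = callsets[i], callsets[j]
            if a.sample != b.sample:
                warnings.warn(
                    f"skipping cross-sample pair {a.replicate_id} vs "
                    f"{b.replicate_id} ({a.sample} != {b.sample})"
                )
                continue
            kinds = kinds_lookup.get(
                frozenset((a.replicate_id, b.replicate_id)), ""
            )
            for truth, test in ((a, b), (b, a)):
                rep = compare(truth, test, intervals, truth_exhaustive=True)
                row = rep.as_dict()
                row["comparison_kinds"] = kinds
                rows.append(row)
    cols = [
        "truth_id",
        "test_id",
        "comparison_kinds",
        "n_joint",
        "n_truth_nonref",
        "n_test_nonref",
        "concordance",
        "nrs",
        "nrc",
        "precision",
    ]
    return pd.DataFrame(rows)[cols]
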