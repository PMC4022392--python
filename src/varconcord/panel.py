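"""Site-level evaluation of a callset against a validated gene-panel truth set.

A panel truth set enumerates, inside its target intervals, both confirmed
non-reference sites and confirmed reference ("ref-confirmed") sites.  Each
truth site receives exactly one category:

* ``tp``  — a PASSing test call with the identical variant key exists,
* ``diff_allele`` — the test calls a variant at the site with a different
  alternate allele (detected at the site level, discordant at the allele
  level),
* ``fn``  — no PASSing test call at the site,
* ``tn``  — ref-confirmed site with no test call.

Test calls matching no truth site are a mix of false positives and "excess"
positives (variants never validated either way) and are tallied together as
``fp_ep``.  Site-level sensitivity counts different-allele sites as
detected: sensitivity = (tp + diff_allele) / (tp + fn + diff_allele).  The
genotype-aware NRC uses only genotype-exact true positives over the same
denominator.  Single-base indels inside long homopolymer runs are the
dominant false-negative class, so the FN report annotates each missed site
with its homopolymer run length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .intervals import IntervalSet
from .variants import Callset, FilterStatus, GenotypeClass, Variant

__all__ = [
    "SiteTally",
    "site_eval",
    "fn_report",
    "homopolymer_run_length",
    "sensitivity_from_counts",
    "HOMOPOLYMER_FLAG_MIN",
]

#: Shortest run length flagged as a homopolymer context.
HOMOPOLYMER_FLAG_MIN = 10


@dataclass
class SiteTally:
    """Site-level confusion tallies against a panel truth set."""

    n_variants: int
    tp: int
    fp_ep: int
    fn: int
    tn: int
    diff_allele: int
    tp_genotype_exact: int
    fp_at_refconfirmed: int
    records: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    @property
    def n_truth_nonref(self) -> int:
        return self.tp + self.fn + self.diff_allele

    @property
    def sensitivity(self) -> Optional[float]:
        den = self.n_truth_nonref
        return (self.tp + self.diff_allele) / den if den else None

    @property
    def nrc(self) -> Optional[float]:
        den = self.n_truth_nonref
        return self.tp_genotype_exact / den if den else None

    @property
    def specificity(self) -> Optional[float]:
        den = self.tn + self.fp_at_refconfirmed
        return self.tn / den if den else None


def sensitivity_from_counts(tp: int, fn: int, diff_allele: int) -> float:
    """Site-level sensitivity with different-allele sites counted as
    detected in both numerator and denominator."""
    return (tp + diff_allele) / (tp + fn + diff_allele)


def _truth_status(call) -> str:
    status = call.annotations.get("STATUS")
    if status is None:
        status = "nonref" if call.is_nonref else "ref-confirmed"
        if call.gclass is GenotypeClass.NOCALL:
            raise ValueError(
                f"truth record {call.variant} lacks a STATUS "
                "(nonref | ref-confirmed) annotation"
            )
        return status
    if status not in ("nonref", "ref-confirmed"):
        raise ValueError(f"bad STATUS {status!r} at {call.variant}")
    return status


def site_eval(
    truth: Callset, test: Callset, intervals: Optional[IntervalSet] = None
) -> SiteTally:
    """Classify every truth site and every PASSing test call in the target.

    Truth records must be normalized/left-aligned and carry a status of
    ``nonref`` or ``ref-confirmed`` (a STATUS annotation; genotype class is
    used as fallback for genotyped truth records).  Only PASSing
    non-reference test calls participate: a called-but-filtered variant is
    a false negative at the site level.
    """
    if intervals is not None:
        truth = truth.restrict(intervals)
        test = test.restrict(intervals)

    truth_nonref: dict[tuple, list] = {}
    truth_refconf_pos: set[tuple] = set()
    truth_by_pos: dict[tuple, list] = {}
    for call in truth:
        status = _truth_status(call)
        if status == "nonref":
            truth_nonref[call.variant.key] = call
            truth_by_pos.setdefault(
                (call.variant.chrom, call.variant.pos), []
            ).append(call)
        else:
            truth_refconf_pos.add((call.variant.chrom, call.variant.pos))

    test_calls = [
        c
        for c in test
        if c.filter_status is FilterStatus.PASS and c.is_nonref
    ]
    test_by_key = {c.variant.key: c for c in test_calls}
    test_by_pos: dict[tuple, list] = {}
    for c in test_calls:
        test_by_pos.setdefault((c.variant.chrom, c.variant.pos), []).append(c)

    records = []
    tp = fn = diff = tn = fp_ep = gt_exact = fp_refconf = 0

    # truth-side classification
    diff_sites: set[tuple] = set()
    for key, call in truth_nonref.items():
        v = call.variant
        pos_key = (v.chrom, v.pos)
        if key in test_by_key:
            tp += 1
            test_call = test_by_key[key]
            exact = test_call.gclass is call.gclass
            gt_exact += int(exact)
            cat = "tp" if exact else "tp_gt_mismatch"
        elif pos_key in test_by_pos:
            diff += 1
            diff_sites.add(pos_key)
            cat = "diff_allele"
        else:
            fn += 1
            cat = "fn"
        records.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "category": "tp" if cat == "tp_gt_mismatch" else cat,
                "genotype_exact": cat == "tp",
                "truth_gclass": call.gclass.value,
            }
        )
    for chrom, pos in sorted(truth_refconf_pos):
        if (chrom, pos) in test_by_pos:
            fp_refconf += 1  # counted below among fp_ep via the call loop
        else:
            tn += 1
            records.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ".",
                    "alt": ".",
                    "category": "tn",
                    "genotype_exact": True,
                    "truth_gclass": "HOMREF",
                }
            )

    # test-side classification of unmatched calls
    consumed_diff: set[tuple] = set()
    for c in test_calls:
        v = c.variant
        pos_key = (v.chrom, v.pos)
        if v.key in truth_nonref:
            continue  # the tp above
        if pos_key in diff_sites and pos_key not in consumed_diff:
            consumed_diff.add(pos_key)
            continue  # the one call explaining the different-allele site
        fp_ep += 1
        records.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "category": "fp_ep",
                "genotype_exact": False,
                "truth_gclass": "",
            }
        )

    return SiteTally(
        n_variants=len(test_calls),
        tp=tp,
        fp_ep=fp_ep,
        fn=fn,
        tn=tn,
        diff_allele=diff,
        tp_genotype_exact=gt_exact,
        fp_at_refconfirmed=fp_refconf,
        records=pd.DataFrame(records),
    )


def homopolymer_run_length(
    context: str, context_start: int, variant: Variant
) -> int:
    """Longest single-base run in ``context`` overlapping the variant span.

    ``context_start`` is the 1-based position of the first context base.
    The span covers the reference bases the variant touches; for a pure
    insertion the anchor base and its right neighbour.
    """
    context = context.upper()
    span_lo = variant.pos
    span_hi = variant.pos + max(len(variant.ref), 2) - 1
    best = 0
    i = 0
    n = len(context)
    while i < n:
        j = i
        while j < n and context[j] == context[i]:
            j += 1
        run_lo = context_start + i
        run_hi = context_start + j - 1
        if run_lo <= span_hi and run_hi >= span_lo:
            best = max(best, j - i)
        i = j
    return best


def fn_report(
    tally: SiteTally,
    contexts: dict[str, tuple[str, int]],
    replicate_callsets: Sequence[Callset] = (),
) -> pd.DataFrame:
    """Describe each missed or different-allele truth site.

    ``contexts`` maps chromosome → (sequence, 1-based start of window)
    covering the FN positions.  When replicate callsets are supplied, each
    row reports in how many of them the site was called PASSing
    (``called_in`` as "k/n").
    """
    if tally.records.empty:
        return pd.DataFrame()
    misses = tally.records[
        tally.records.category.isin(["fn", "diff_allele"])
    ].copy()
    rows = []
    n_reps = len(replicate_callsets)
    for _, rec in misses.iterrows():
        variant = Variant(rec.chrom, int(rec.pos), rec.ref, rec.alt)
        run = 0
        if rec.chrom in contexts:
            seq, start = contexts[rec.chrom]
            run = homopolymer_run_length(seq, start, variant)
        called = sum(
            1
            for cs in replicate_callsets
            if (c := cs.get(variant)) is not None
            and c.filter_status is FilterStatus.PASS
            and c.is_nonref
        )
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": int(rec.pos),
                "ref": rec.ref,
                "alt": rec.alt,
                "truth_genotype": rec.truth_gclass,
                "category": rec.category,
                "called_in": f"{called}/{n_reps}" if n_reps else "",
                "homopolymer_run": run,
                "homopolymer_flag": run >= HOMOPOLYMER_FLAG_MIN,
            }
        )
    return pd.DataFrame(rows)
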