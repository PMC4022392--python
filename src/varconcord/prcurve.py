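"""Precision vs NRC as a function of the variant-quality threshold.

The variant filter (VQSR) attaches a log-odds score (VQSLOD) to each call
and PASSes calls above a tranche cut chosen to capture 99.5% of known true
positives.  Sweeping that cut trades recall for precision: at each
threshold ``t`` every scored call with VQSLOD ≥ t is treated as PASSing and
every other call as a no-call, and precision and non-reference genotype
concordance (NRC) are recomputed against the truth set.  A well-placed
operating point sits at the inflection where relaxing the threshold admits
about as many false positives as true positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .concordance import compare
from .intervals import IntervalSet
from .variants import Callset, FilterStatus, GenotypeClass, VariantClass

__all__ = ["PRCurve", "pr_sweep", "marginal_ratio", "SCORE_KEY"]

SCORE_KEY = "VQSLOD"
MAX_AUTO_THRESHOLDS = 200


@dataclass
class PRCurve:
    """An ordered precision/NRC sweep plus the callset's own operating point.

    ``points`` columns: threshold, n_pass, tp, fp, precision, nrc —
    thresholds strictly increasing, n_pass and nrc non-increasing.  ``tp``
    counts passing test calls matching the truth genotype exactly; ``fp``
    the remaining passing non-reference calls in the precision denominator.
    """

    points: pd.DataFrame
    operating_point: tuple  # (precision, nrc) at the stored FILTER status
    vtype: VariantClass
    truth_scope: str = "all"
    n_unscored: int = 0


def _auto_thresholds(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    if distinct.size <= MAX_AUTO_THRESHOLDS:
        return distinct
    # deterministic quantile thinning to a bounded grid
    qs = np.linspace(0, 1, MAX_AUTO_THRESHOLDS)
    idx = np.unique((qs * (distinct.size - 1)).round().astype(int))
    return distinct[idx]


def pr_sweep(
    test: Callset,
    truth: Callset,
    intervals: Optional[IntervalSet] = None,
    vtype: VariantClass = VariantClass.SNV,
    thresholds: Union[str, Sequence[float]] = "auto",
    truth_exhaustive: Optional[bool] = None,
) -> PRCurve:
    """Sweep the quality threshold for one variant class.

    Test calls lacking a VQSLOD annotation are excluded from the sweep and
    reported as ``n_unscored`` (the paper's pipeline applies fixed filters,
    not VQSR, to exome indels, so score-free calls have no defined place on
    the curve).  The operating point uses the stored FILTER field instead of
    a score cut.
    """
    if truth_exhaustive is None:
        truth_exhaustive = truth.exhaustive
    if intervals is not None:
        truth = truth.restrict(intervals)
        test = test.restrict(intervals)
    truth = truth.subset(vtype)
    test = test.subset(vtype)

    operating = compare(truth, test, None, truth_exhaustive=truth_exhaustive)
    op_point = (operating.precision, operating.nrc)

    scored = [c for c in test if SCORE_KEY in c.annotations]
    n_unscored = len(test) - len(scored)
    if not scored:
        raise ValueError(f"no {vtype.value} calls carry a {SCORE_KEY} score")

    # flatten the join once; each sweep point is then pure numpy
    truth_nonref_keys = {
        c.variant.key for c in truth if c.is_nonref and
        c.filter_status is FilterStatus.PASS
    }
    truth_class = {
        c.variant.key: c.gclass
        for c in truth
        if c.filter_status is FilterStatus.PASS
    }
    n_truth_nonref = len(truth_nonref_keys)

    score = np.array([c.annotations[SCORE_KEY] for c in scored], dtype=float)
    is_nonref = np.array([c.is_nonref for c in scored])
    in_truth = np.array([c.variant.key in truth_class for c in scored])
    gt_match = np.array(
        [truth_class.get(c.variant.key) is c.gclass for c in scored]
    )
    match_nonref = gt_match & is_nonref

    if isinstance(thresholds, str):
        if thresholds != "auto":
            raise ValueError(f"unknown threshold spec {thresholds!r}")
        grid = _auto_thresholds(score)
    else:
        grid = np.asarray(sorted(set(float(t) for t in thresholds)))
        if grid.size == 0:
            raise ValueError("empty threshold list")

    rows = []
    for t in grid:
        passing = score >= t
        tp = int((passing & match_nonref).sum())
        if truth_exhaustive:
            denom_mask = passing & is_nonref
        else:
            denom_mask = passing & is_nonref & in_truth
        fp = int(denom_mask.sum()) - tp
        precision = tp / (tp + fp) if (tp + fp) > 0 else None
        nrc = tp / n_truth_nonref if n_truth_nonref > 0 else None
        rows.append(
            {
                "threshold": float(t),
                "n_pass": int(passing.sum()),
                "tp": tp,
                "fp": fp,
                "precision": precision,
                "nrc": nrc,
            }
        )
    return PRCurve(
        points=pd.DataFrame(rows),
        operating_point=op_point,
        vtype=vtype,
        n_unscored=n_unscored,
    )


def marginal_ratio(curve: PRCurve) -> pd.DataFrame:
    """Newly admitted true/false positives between consecutive thresholds.

    Rows follow the relaxation direction (descending threshold): between the
    tighter cut ``threshold_high`` and the looser ``threshold_low``, ``d_tp``
    and ``d_fp`` count the additional agreeing and disagreeing/unconfirmed
    calls admitted, and ``ratio`` their quotient (``inf`` when no false
    positives enter).  ``brackets_unity`` flags the interval(s) where the
    ratio crosses 1 — the filter's natural inflection point.
    """
    pts = curve.points
    if len(pts) < 2:
        return pd.DataFrame(
            columns=[
                "threshold_high",
                "threshold_low",
                "d_tp",
                "d_fp",
                "ratio",
                "brackets_unity",
            ]
        )
    desc = pts.sort_values("threshold", ascending=False).reset_index(drop=True)
    rows = []
    for i in range(len(desc) - 1):
        hi, lo = desc.iloc[i], desc.iloc[i + 1]
        d_tp = int(lo.tp - hi.tp)
        d_fp = int(lo.fp - hi.fp)
        ratio = d_tp / d_fp if d_fp > 0 else float("inf")
        rows.append(
            {
                "threshold_high": hi.threshold,
                "threshold_low": lo.threshold,
                "d_tp": d_tp,
                "d_fp": d_fp,
                "ratio": ratio,
            }
        )
    out = pd.DataFrame(rows)
    r = out.ratio.to_numpy()
    brackets = np.zeros(len(out), dtype=bool)
    for i in range(len(out)):
        if r[i] == 1.0:
            brackets[i] = True
        elif i + 1 < len(out) and (r[i] - 1.0) * (r[i + 1] - 1.0) < 0:
            brackets[i] = True
            brackets[i + 1] = True
    out["brackets_unity"] = brackets
    return out
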