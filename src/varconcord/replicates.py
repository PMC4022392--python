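"""Technical-replicate reproducibility: call uniformity across replicates,
pairwise comparison-kind classification, and the regression of concordance
on comparison kinds.

Replicates are named *sample/run-machine-slot* and carry library, run,
machine and sequencing-mode provenance.  A pair of replicates is classified
by every kind of comparison it represents (a pair may represent several at
once): same run and machine → intra-run; same machine, different run →
inter-run; different machine → inter-machine; different mode (high-
throughput vs rapid) → inter-mode; different library preparation →
inter-library.

Call uniformity deliberately ignores the variant filter: a site counts as
"called" in a replicate when the replicate emits the variant key at all,
PASSing or not, because non-uniformity in which variants the caller emits
is a distinct failure mode from filtering differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .intervals import IntervalSet
from .variants import Callset, VariantClass

__all__ = [
    "COMPARISON_KINDS",
    "UniformityTable",
    "ComparisonDesign",
    "RegressionResult",
    "uniformity",
    "derive_kinds",
    "build_design",
    "regress_concordance",
]

COMPARISON_KINDS = [
    "intra-run",
    "inter-run",
    "inter-machine",
    "inter-mode",
    "inter-library",
]

_PROVENANCE_FIELDS = ("library", "run", "machine", "mode")


@dataclass
class UniformityTable:
    """Partition of the union of called sites by replicate support.

    ``pct[k]`` is the percentage of the (optionally interval-restricted)
    union of variant keys observed in exactly ``k`` of the ``n`` replicates;
    ``n_private[rep]`` counts keys seen only in that replicate.
    """

    sample: str
    assay: str
    vtype: VariantClass
    n_replicates: int
    restriction: str
    counts: dict  # k -> number of union keys seen in exactly k replicates
    pct: dict  # k -> percentage of the union
    n_private: dict  # replicate_id -> count of keys private to it
    n_union: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": list(self.counts),
                "count": list(self.counts.values()),
                "pct": [self.pct[k] for k in self.counts],
            }
        )


def uniformity(
    callsets: Sequence[Callset],
    vtype: VariantClass = VariantClass.SNV,
    restriction: Optional[IntervalSet] = None,
    restriction_label: Optional[str] = None,
) -> UniformityTable:
    """Partition the union of emitted sites by how many replicates carry them.

    Presence is site-level and filter-blind (a FILTERED call still counts).
    """
    if len(callsets) < 2:
        raise ValueError("need at least two replicates")
    samples = {c.sample for c in callsets}
    if len(samples) != 1:
        raise ValueError(f"mixed samples in uniformity analysis: {sorted(samples)}")
    assays = {c.provenance.get("assay", "") for c in callsets}

    key_sets = []
    for cs in callsets:
        keys = {
            c.variant.key
            for c in cs
            if c.variant.vclass is vtype
            and (
                restriction is None
                or restriction.contains(c.variant.chrom, c.variant.pos - 1)
            )
        }
        key_sets.append(keys)
    union = set().union(*key_sets)
    n = len(callsets)
    support = {key: sum(key in ks for ks in key_sets) for key in union}
    counts = {k: 0 for k in range(1, n + 1)}
    for s in support.values():
        counts[s] += 1
    total = len(union)
    pct = {
        k: (100.0 * v / total if total else 0.0) for k, v in counts.items()
    }
    n_private = {
        cs.replicate_id: sum(
            1 for key in ks if support[key] == 1
        )
        for cs, ks in zip(callsets, key_sets)
    }
    return UniformityTable(
        sample=callsets[0].sample,
        assay=next(iter(assays)),
        vtype=vtype,
        n_replicates=n,
        restriction=restriction_label
        or ("none" if restriction is None else "restricted"),
        counts=counts,
        pct=pct,
        n_private=n_private,
        n_union=total,
    )


def derive_kinds(a: dict, b: dict) -> frozenset:
    """Comparison kinds represented by a pair, from their provenance dicts."""
    kinds = set()
    if a["run"] == b["run"] and a["machine"] == b["machine"]:
        kinds.add("intra-run")
    if a["machine"] == b["machine"] and a["run"] != b["run"]:
        kinds.add("inter-run")
    if a["machine"] != b["machine"]:
        kinds.add("inter-machine")
    if a["mode"] != b["mode"]:
        kinds.add("inter-mode")
    if a["library"] != b["library"]:
        kinds.add("inter-library")
    return frozenset(kinds)


@dataclass
class ComparisonDesign:
    """All unordered same-sample replicate pairs with their kind labels.

    ``pairs`` rows are (replicate_a, replicate_b, kinds, primary_label);
    ``primary_label`` is the kind itself when the pair represents exactly
    one kind, else "other" (display only — the kind indicators used in the
    regression are non-exclusive).
    """

    pairs: list = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for a, b, kinds, label in self.pairs:
            row = {"replicate_a": a, "replicate_b": b, "primary_label": label}
            for kind in COMPARISON_KINDS:
                row[kind] = kind in kinds
            rows.append(row)
        return pd.DataFrame(rows)


def build_design(
    design_table: pd.DataFrame, samples: Optional[Sequence[str]] = None
) -> ComparisonDesign:
    """Classify every unordered same-sample, same-assay replicate pair."""
    df = design_table
    if samples is not None:
        df = df[df["sample"].isin(list(samples))]
    for idx, row in df.iterrows():
        for f in _PROVENANCE_FIELDS:
            if f not in row or pd.isna(row[f]) or row[f] == "":
                raise ValueError(
                    f"design row {row.get('replicate_id', idx)!r} missing "
                    f"provenance field {f!r}"
                )
    pairs = []
    rows = df.to_dict("records")
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i], rows[j]
            if a["sample"] != b["sample"]:
                continue
            if a.get("assay") != b.get("assay"):
                continue
            kinds = derive_kinds(a, b)
            label = next(iter(kinds)) if len(kinds) == 1 else "other"
            pairs.append((a["replicate_id"], b["replicate_id"], kinds, label))
    return ComparisonDesign(pairs)


@dataclass
class RegressionResult:
    """OLS of pairwise concordance on comparison-kind indicators.

    The joint model (all kind indicators + sample controls) is tested
    against the sample-only null with a nested F-test; each kind is then
    tested individually (that kind + sample controls), Bonferroni-corrected
    at ``alpha_overall / n_kinds_tested``.  Coefficients are additive
    changes in concordance.
    """

    coefficients: pd.Series
    std_errors: pd.Series
    overall_pvalue: float
    perkind_pvalues: pd.Series
    n_pairs: int
    kinds_tested: list
    kinds_dropped: list
    kinds_baseline: list = field(default_factory=list)
    alpha_overall: float = 0.05

    @property
    def alpha_perkind(self) -> float:
        return self.alpha_overall / max(len(self.kinds_tested), 1)

    @property
    def significant_kinds(self) -> list:
        return [
            k for k in self.kinds_tested if self.perkind_pvalues[k] < self.alpha_perkind
        ]


def _pair_concordances(reports: pd.DataFrame) -> dict:
    """Collapse a (possibly two-direction) report table to one symmetric
    concordance value per unordered pair."""
    values: dict[frozenset, float] = {}
    for _, row in reports.iterrows():
        key = frozenset((row["truth_id"], row["test_id"]))
        c = row["concordance"]
        if key in values and not np.isclose(values[key], c):
            raise ValueError(f"asymmetric concordance for pair {sorted(key)}")
        values[key] = float(c)
    return values


def regress_concordance(
    design: ComparisonDesign,
    reports: pd.DataFrame,
    alpha_overall: float = 0.05,
) -> RegressionResult:
    """Regress symmetric pairwise concordance on kind indicators with the
    sample identity as control covariates."""
    values = _pair_concordances(reports)
    rows = []
    rep_sample = {}
    for a, b, kinds, _label in design.pairs:
        key = frozenset((a, b))
        if key not in values:
            continue
        row = {kind: float(kind in kinds) for kind in COMPARISON_KINDS}
        row["concordance"] = values[key]
        row["_pair"] = (a, b)
        rows.append(row)
    if len(rows) < 3:
        raise ValueError("too few pairs with concordance values to regress")
    df = pd.DataFrame(rows)

    kinds_tested, kinds_dropped = [], []
    for kind in COMPARISON_KINDS:
        if df[kind].nunique() > 1:
            kinds_tested.append(kind)
        else:
            kinds_dropped.append(kind)
            if df[kind].iloc[0] == 1.0:
                warnings.warn(f"kind {kind!r} constant across pairs; dropped")

    # sample controls: one indicator per non-reference sample level
    if "sample" in reports.columns:
        pair_samples = {}
        for _, r in reports.iterrows():
            pair_samples[frozenset((r["truth_id"], r["test_id"]))] = r["sample"]
        df["_sample"] = [pair_samples[frozenset(p)] for p in df["_pair"]]
    else:
        # infer the sample from the replicate-id prefix "sample/..." if present
        df["_sample"] = [
            p[0].split("/")[0] if "/" in p[0] else "" for p in df["_pair"]
        ]
    sample_dummies = pd.get_dummies(df["_sample"], prefix="sample", drop_first=True)
    sample_cols = [c for c in sample_dummies.columns if sample_dummies[c].nunique() > 1]
    controls = sample_dummies[sample_cols].astype(float)

    y = df["concordance"].to_numpy(dtype=float)
    X_null = sm.add_constant(controls, has_constant="add")

    # The run/machine kinds partition the pairs (every pair is exactly one of
    # intra-run / inter-run / inter-machine), which makes the joint design
    # collinear with the intercept; drop kinds as baseline categories until
    # the matrix has full rank, starting from the most-similar comparison.
    kinds_joint = list(kinds_tested)
    kinds_baseline: list = []
    baseline_order = list(COMPARISON_KINDS)
    while True:
        X_full = sm.add_constant(
            pd.concat([df[kinds_joint].astype(float), controls], axis=1),
            has_constant="add",
        )
        if np.linalg.matrix_rank(X_full.to_numpy()) == X_full.shape[1]:
            break
        drop = next(k for k in baseline_order if k in kinds_joint)
        kinds_joint.remove(drop)
        kinds_baseline.append(drop)
    fit_full = sm.OLS(y, X_full).fit()
    fit_null = sm.OLS(y, X_null).fit()
    f_stat, overall_p, _ = fit_full.compare_f_test(fit_null)

    perkind = {}
    for kind in kinds_tested:
        X_k = sm.add_constant(
            pd.concat([df[[kind]].astype(float), controls], axis=1),
            has_constant="add",
        )
        perkind[kind] = float(sm.OLS(y, X_k).fit().pvalues[kind])

    return RegressionResult(
        coefficients=fit_full.params,
        std_errors=fit_full.bse,
        overall_pvalue=float(overall_p),
        perkind_pvalues=pd.Series(perkind),
        n_pairs=len(df),
        kinds_tested=kinds_tested,
        kinds_dropped=kinds_dropped,
        kinds_baseline=kinds_baseline,
        alpha_overall=alpha_overall,
    )
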