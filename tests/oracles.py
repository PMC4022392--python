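"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately naive — plain dict/set comparisons and
per-base scans — and shares no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np

from varconcord.variants import (
    Callset,
    FilterStatus,
    GenotypeCall,
    GenotypeClass,
    Variant,
)

NONREF = ("HET", "HOMALT")
GENOTYPED = ("HOMREF", "HET", "HOMALT")


def effective_classes(callset: Callset) -> dict:
    """key -> effective class string, with FILTERED treated as NOCALL."""
    out = {}
    for call in callset:
        if call.filter_status is FilterStatus.FILTERED:
            out[call.variant.key] = "NOCALL"
        else:
            out[call.variant.key] = call.gclass.value
    return out


def brute_force_matrix(truth: Callset, test: Callset) -> dict:
    """Cell counts {(truth_class, test_class): n} by direct set comparison."""
    t = effective_classes(truth)
    s = effective_classes(test)
    cells: dict = {}
    for key in set(t) | set(s):
        cell = (t.get(key, "ABSENT"), s.get(key, "ABSENT"))
        cells[cell] = cells.get(cell, 0) + 1
    return cells


def brute_force_metrics(truth: Callset, test: Callset) -> dict:
    """The four metrics straight from their definitions (truth exhaustive
    convention: every test non-ref call is in the precision denominator)."""
    cells = brute_force_matrix(truth, test)

    def total(pred):
        return sum(n for cell, n in cells.items() if pred(*cell))

    n_joint = total(lambda a, b: a in GENOTYPED and b in GENOTYPED)
    conc_num = total(lambda a, b: a in GENOTYPED and a == b)
    truth_nr = total(lambda a, b: a in NONREF)
    nrs_num = total(lambda a, b: a in NONREF and b in NONREF)
    nrc_num = total(lambda a, b: a in NONREF and a == b)
    test_nr = total(lambda a, b: b in NONREF)

    div = lambda p, q: (p / q) if q else None  # noqa: E731
    return {
        "total": sum(cells.values()),
        "concordance": div(conc_num, n_joint),
        "nrs": div(nrs_num, truth_nr),
        "nrc": div(nrc_num, truth_nr),
        "precision": div(nrc_num, test_nr),
    }


def random_callset_pair(rng: np.random.Generator, max_sites: int = 1000):
    """Two random callsets sharing a pool of variant keys, exercising every
    genotype class, filter status and one-sided absence."""
    n = int(rng.integers(5, max_sites + 1))
    classes = [
        GenotypeClass.HOMREF,
        GenotypeClass.HET,
        GenotypeClass.HOMALT,
        GenotypeClass.NOCALL,
    ]
    a = Callset("A", "S")
    b = Callset("B", "S")
    alts = "ACGT"
    for i in range(n):
        pos = i + 1
        ref = alts[int(rng.integers(4))]
        alt = alts[(alts.index(ref) + int(rng.integers(1, 4))) % 4]
        v = Variant("chr1", pos, ref, alt)
        for cs in (a, b):
            r = rng.random()
            if r < 0.2:
                continue  # absent from this side
            gclass = classes[int(rng.integers(4))]
            fstatus = (
                FilterStatus.FILTERED if rng.random() < 0.15 else FilterStatus.PASS
            )
            cs.add(GenotypeCall(v, gclass, fstatus))
    return a, b


def brute_force_site_classify(truth_status: dict, test_calls: set) -> dict:
    """Panel site categories by direct enumeration.

    ``truth_status`` maps (chrom, pos, ref, alt) -> "nonref"/"ref-confirmed";
    ``test_calls`` is the set of PASSing non-ref test keys.
    """
    test_pos = {(k[0], k[1]) for k in test_calls}
    tallies = {"tp": 0, "fn": 0, "diff_allele": 0, "tn": 0, "fp_ep": 0}
    nonref_keys = {k for k, s in truth_status.items() if s == "nonref"}
    for key, status in truth_status.items():
        at_pos = (key[0], key[1]) in test_pos
        if status == "nonref":
            if key in test_calls:
                tallies["tp"] += 1
            elif at_pos:
                tallies["diff_allele"] += 1
            else:
                tallies["fn"] += 1
        else:
            if not at_pos:
                tallies["tn"] += 1
    nonref_pos = {(k[0], k[1]) for k in nonref_keys}
    exactly_matched_pos = {
        (k[0], k[1]) for k in test_calls if k in nonref_keys
    }
    claimed_diff = set()
    for key in sorted(test_calls):
        if key in nonref_keys:
            continue
        pos = (key[0], key[1])
        is_diff_site = pos in nonref_pos and pos not in exactly_matched_pos
        if is_diff_site and pos not in claimed_diff:
            claimed_diff.add(pos)  # the one call explaining the diff site
            continue
        tallies["fp_ep"] += 1
    return tallies


def callable_positions(
    depth: np.ndarray, mapq0: np.ndarray, min_depth: int, max_frac: float
) -> np.ndarray:
    """Per-base callable predicate, evaluated position by position."""
    ok = np.zeros(depth.size, dtype=bool)
    for i in range(depth.size):
        ok[i] = depth[i] >= min_depth and (
            depth[i] > 0 and mapq0[i] / depth[i] <= max_frac
        )
    return ok
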