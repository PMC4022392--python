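"""Synthetic fixtures with known error structure.

Every generator here is a pure function of its parameters and a seed, and
each records enough latent truth (sidecar labels, closed-form score
distributions, additive batch-effect models) that downstream metrics can be
checked against analytic expectations:

* a truth callset of SNVs and indels with genotypes,
* a test callset derived from it by a genotype-confusion process — site
  dropout, filter flagging, zygosity errors, different-allele errors,
  uniform false-positive calls, and an extra dropout for indels inside long
  homopolymer runs (the dominant real-data false-negative class),
* per-call quality scores drawn from separated true/artifact distributions
  (emulating VQSLOD),
* per-base coverage tracks with low-depth and high-MAPQ0 patches,
* replicate families whose pairwise concordances follow an additive
  comparison-kind model.

Error events are applied per site in the fixed order miss → different
allele → genotype error → filter, independently with the stated
probabilities, so to first order NRS = (1−p_miss)(1−p_diffallele)
(1−p_filtered) and NRC = NRS·(1−p_gterr).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack
from .intervals import IntervalSet
from .variants import (
    Callset,
    FilterStatus,
    GenotypeCall,
    GenotypeClass,
    Variant,
    VariantClass,
)

__all__ = [
    "ConfusionModel",
    "ScoreModel",
    "BatchEffectModel",
    "gen_reference_context",
    "gen_truth_callset",
    "corrupt",
    "gen_coverage",
    "gen_replicate_family",
    "reference_design",
]

_BASES = np.array(list("ACGT"))


@dataclass
class ConfusionModel:
    """Independent per-site error probabilities for the corruption process."""

    p_miss: float = 0.04
    p_filtered: float = 0.01
    p_gterr: float = 0.01
    p_diffallele: float = 0.002
    p_fp_per_kb: float = 0.1
    indel_homopolymer_dropout: float = 0.9
    run_min: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_miss",
            "p_filtered",
            "p_gterr",
            "p_diffallele",
            "indel_homopolymer_dropout",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_fp_per_kb < 0:
            raise ValueError("p_fp_per_kb must be >= 0")


@dataclass
class ScoreModel:
    """Gaussian quality-score distributions for true and artifactual calls.

    The closed-form survival functions give the analytic ROC at any
    threshold: recall(t) = true_sf(t), artifact pass rate = artifact_sf(t).
    """

    true_loc: float = 10.0
    true_scale: float = 3.0
    artifact_loc: float = 0.0
    artifact_scale: float = 3.0

    def true_sf(self, t):
        return stats.norm.sf(t, loc=self.true_loc, scale=self.true_scale)

    def artifact_sf(self, t):
        return stats.norm.sf(t, loc=self.artifact_loc, scale=self.artifact_scale)

    def crossover(self, n_true: int, n_artifact: int) -> float:
        """Score where the weighted densities cross (equal marginal TP/FP),
        assuming equal scales."""
        if not np.isclose(self.true_scale, self.artifact_scale):
            raise ValueError("crossover defined here for equal scales only")
        mid = (self.true_loc + self.artifact_loc) / 2.0
        if n_true == n_artifact:
            return mid
        s2 = self.true_scale**2
        return mid + s2 * np.log(n_artifact / n_true) / (
            self.true_loc - self.artifact_loc
        )


def gen_reference_context(
    length: int,
    homopolymer_spec: Sequence[tuple] = (),
    seed: int = 0,
    max_background_run: int = 4,
) -> str:
    """Random sequence with embedded homopolymer tracts.

    ``homopolymer_spec`` entries are (offset, base, run_length) with 0-based
    offsets.  Background sequence never exceeds ``max_background_run``
    consecutive identical bases, so the only long runs are the requested
    ones.  Overlapping requested runs are an error.
    """
    spans = sorted((off, off + n, b) for off, b, n in homopolymer_spec)
    prev_end = -1
    for off, end, b in spans:
        if off <= prev_end:
            raise ValueError("overlapping homopolymer runs")
        if end > length or off < 0:
            raise ValueError("homopolymer run outside sequence")
        prev_end = end - 1
    rng = np.random.default_rng(seed)
    seq = [""] * length
    for off, end, b in spans:
        for i in range(off, end):
            seq[i] = b.upper()
    run_char, run_len = "", 0
    for i in range(length):
        if seq[i]:
            run_char, run_len = seq[i], 0  # reset at requested tracts
            continue
        choices = [c for c in "ACGT" if not (c == run_char and run_len >= max_background_run)]
        # avoid extending a requested tract at its edges
        if i > 0 and seq[i - 1] and seq[i - 1] in choices:
            left = seq[i - 1]
            choices = [c for c in choices if c != left]
        if i + 1 < length and seq[i + 1] and seq[i + 1] in choices:
            choices = [c for c in choices if c != seq[i + 1]]
        c = choices[rng.integers(len(choices))]
        if c == run_char:
            run_len += 1
        else:
            run_char, run_len = c, 1
        seq[i] = c
    return "".join(seq)


def _positions_in(intervals: IntervalSet) -> np.ndarray:
    """All 1-based positions covered by the intervals, as a flat array of
    (chrom index, pos) with a parallel chromosome list."""
    chroms, pos = [], []
    for ci, (c, s, e) in enumerate(intervals):
        chroms.append(c)
        pos.append(np.stack([np.full(e - s, ci), np.arange(s + 1, e + 1)], axis=1))
    return chroms, np.concatenate(pos) if pos else np.empty((0, 2), dtype=int)


def gen_truth_callset(
    n_sites: int,
    intervals: IntervalSet,
    snv_frac: float = 0.9,
    genotype_mix: tuple = (0.6, 0.4),
    seed: int = 0,
    sample: str = "SIM",
    replicate_id: Optional[str] = None,
    exhaustive: bool = False,
) -> Callset:
    """A truth callset of distinct sites inside the intervals.

    ``genotype_mix`` gives the (HET, HOMALT) proportions.  Insertions and
    deletions are drawn evenly among the non-SNV fraction, with 1–3 bp
    repeat units.
    """
    if abs(sum(genotype_mix) - 1.0) > 1e-9:
        raise ValueError("genotype_mix must sum to 1")
    if n_sites > intervals.total_bases:
        raise ValueError(
            f"{n_sites} sites requested but intervals cover only "
            f"{intervals.total_bases} bases"
        )
    rng = np.random.default_rng(seed)
    chrom_names, coords = _positions_in(intervals)
    pick = rng.choice(len(coords), size=n_sites, replace=False)
    coords = coords[np.sort(pick)]

    is_snv = rng.random(n_sites) < snv_frac
    het = rng.random(n_sites) < genotype_mix[0]
    ref_idx = rng.integers(0, 4, n_sites)
    alt_shift = rng.integers(1, 4, n_sites)
    ins = rng.random(n_sites) < 0.5
    unit_len = rng.integers(1, 4, n_sites)
    unit_idx = rng.integers(0, 4, (n_sites, 3))

    calls = []
    for i in range(n_sites):
        chrom = chrom_names[coords[i, 0]]
        pos = int(coords[i, 1])
        ref_base = _BASES[ref_idx[i]]
        if is_snv[i]:
            ref, alt = ref_base, _BASES[(ref_idx[i] + alt_shift[i]) % 4]
        else:
            unit = "".join(_BASES[unit_idx[i, : unit_len[i]]])
            if ins[i]:
                ref, alt = ref_base, ref_base + unit
            else:
                ref, alt = ref_base + unit, ref_base
        gclass = GenotypeClass.HET if het[i] else GenotypeClass.HOMALT
        calls.append(GenotypeCall(Variant(chrom, pos, str(ref), str(alt)), gclass))
    return Callset(
        replicate_id or f"{sample}/truth",
        sample,
        calls,
        provenance={"assay": "reference"},
        exhaustive=exhaustive,
    )


def _other_alt(variant: Variant, rng) -> Variant:
    """A different alternate allele at the same site."""
    if variant.vclass is VariantClass.SNV:
        for _ in range(10):
            alt = str(_BASES[rng.integers(0, 4)])
            if alt not in (variant.ref, variant.alt):
                return Variant(variant.chrom, variant.pos, variant.ref, alt)
    # indels / fallback: extend the alt by one base
    alt = variant.alt + str(_BASES[rng.integers(0, 4)])
    if alt == variant.ref:
        alt += "A"
    return Variant(variant.chrom, variant.pos, variant.ref, alt)


def corrupt(
    truth: Callset,
    model: ConfusionModel,
    scores: Optional[ScoreModel] = None,
    intervals: Optional[IntervalSet] = None,
    homopolymer_keys: frozenset = frozenset(),
) -> tuple[Callset, pd.DataFrame]:
    """Derive a test callset from a truth callset under a confusion model.

    Returns the corrupted callset and a sidecar table of latent labels
    (one row per truth site and per injected false positive) for exact
    oracle accounting.  ``homopolymer_keys`` marks truth variant keys whose
    indels suffer the extra homopolymer dropout.  False positives are
    placed uniformly over interval bases not occupied by truth sites
    (``intervals`` required when ``p_fp_per_kb > 0``).
    """
    rng = np.random.default_rng(model.seed)
    out = Callset(
        truth.replicate_id + "+corrupt",
        truth.sample,
        provenance=dict(truth.provenance, assay="WGS"),
    )
    sidecar = []
    truth_calls = list(truth)
    n = len(truth_calls)
    u_miss = rng.random(n)
    u_hp = rng.random(n)
    u_diff = rng.random(n)
    u_gterr = rng.random(n)
    u_filter = rng.random(n)
    for i, call in enumerate(truth_calls):
        v = call.variant
        event = "none"
        if u_miss[i] < model.p_miss:
            event = "miss"
        elif (
            v.vclass is VariantClass.INDEL
            and v.key in homopolymer_keys
            and u_hp[i] < model.indel_homopolymer_dropout
        ):
            event = "homopolymer_dropout"
        if event in ("miss", "homopolymer_dropout"):
            sidecar.append(
                {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                 "latent": "true", "event": event, "truth_gclass": call.gclass.value}
            )
            continue
        variant, gclass = v, call.gclass
        if u_diff[i] < model.p_diffallele:
            variant = _other_alt(v, rng)
            event = "diff_allele"
        if u_gterr[i] < model.p_gterr:
            gclass = (
                GenotypeClass.HOMALT
                if gclass is GenotypeClass.HET
                else GenotypeClass.HET
            )
            event = "gterr" if event == "none" else event + "+gterr"
        fstatus = FilterStatus.PASS
        if u_filter[i] < model.p_filtered:
            fstatus = FilterStatus.FILTERED
            event = "filtered" if event == "none" else event + "+filtered"
        annotations = {}
        if scores is not None:
            annotations["VQSLOD"] = float(
                rng.normal(scores.true_loc, scores.true_scale)
            )
        out.add(GenotypeCall(variant, gclass, fstatus, annotations))
        sidecar.append(
            {"chrom": variant.chrom, "pos": variant.pos, "ref": variant.ref,
             "alt": variant.alt, "latent": "true", "event": event,
             "truth_gclass": call.gclass.value}
        )

    if model.p_fp_per_kb > 0:
        if intervals is None:
            raise ValueError("intervals required to place false positives")
        n_fp = int(rng.poisson(model.p_fp_per_kb * intervals.total_bases / 1000.0))
        chrom_names, coords = _positions_in(intervals)
        occupied = {(c.variant.chrom, c.variant.pos) for c in truth_calls}
        occupied |= {(c.variant.chrom, c.variant.pos) for c in out}
        placed = 0
        while placed < n_fp and len(occupied) < len(coords):
            j = int(rng.integers(len(coords)))
            chrom = chrom_names[coords[j, 0]]
            pos = int(coords[j, 1])
            if (chrom, pos) in occupied:
                continue
            occupied.add((chrom, pos))
            ref = str(_BASES[rng.integers(0, 4)])
            alt = str(_BASES["ACGT".index(ref) - rng.integers(1, 4)])
            variant = Variant(chrom, pos, ref, alt)
            annotations = {}
            if scores is not None:
                annotations["VQSLOD"] = float(
                    rng.normal(scores.artifact_loc, scores.artifact_scale)
                )
            out.add(
                GenotypeCall(variant, GenotypeClass.HET, FilterStatus.PASS, annotations)
            )
            sidecar.append(
                {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                 "latent": "artifact", "event": "fp", "truth_gclass": ""}
            )
            placed += 1
    return out, pd.DataFrame(sidecar)


def gen_coverage(
    intervals: IntervalSet,
    base_depth: int = 30,
    low_patches: Sequence[tuple] = (),
    mapq0_patches: Sequence[tuple] = (),
    seed: int = 0,
    poisson_jitter: bool = False,
) -> CoverageTrack:
    """Constant-depth coverage with low-depth and high-MAPQ0 patches.

    ``low_patches`` entries are ((chrom, start, end), depth); 0-based
    half-open patch coordinates.  ``mapq0_patches`` entries are
    ((chrom, start, end), fraction) setting the MAPQ0 read fraction.
    Contradictory overlapping patches of the same kind are an error.
    """
    for patches in (low_patches, mapq0_patches):
        seen = []
        for (c, s, e), _val in patches:
            for (c2, s2, e2) in seen:
                if c == c2 and s < e2 and s2 < e:
                    raise ValueError(f"overlapping patches at {c}:{s}-{e}")
            seen.append((c, s, e))
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, start, end in intervals:
        n = end - start
        depth = np.full(n, base_depth, dtype=np.int64)
        if poisson_jitter:
            depth = rng.poisson(base_depth, n).astype(np.int64)
        frac = np.zeros(n)
        for (c, s, e), d in low_patches:
            if c == chrom:
                lo, hi = max(s, start), min(e, end)
                if lo < hi:
                    depth[lo - start : hi - start] = d
        for (c, s, e), f in mapq0_patches:
            if c == chrom:
                lo, hi = max(s, start), min(e, end)
                if lo < hi:
                    frac[lo - start : hi - start] = f
        mapq0 = np.ceil(frac * depth - 1e-9).astype(np.int64)
        pos = np.arange(start + 1, end + 1)
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "depth": depth, "mapq0": mapq0}
            )
        )
    return CoverageTrack(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Replicate families


def reference_design() -> pd.DataFrame:
    """The replicate-design template used throughout: five reference samples
    sequenced as technical replicates across four run cycles, two machines
    and two modes (run cycle r4 is the rapid mode), with library
    assignments chosen so the pairwise comparisons exercise every
    comparison kind.  Replicates are named *sample/run-machine-slot*."""
    rows = []

    def add(sample, assay, rep, library, mode=None):
        run, machine, _slot = rep.split("-")
        rows.append(
            {
                "replicate_id": f"{sample}/{rep}",
                "sample": sample,
                "library": library,
                "run": run,
                "machine": machine,
                "mode": mode or ("rapid" if run == "r4" else "high-throughput"),
                "assay": assay,
            }
        )

    # WES: 7 NA12878 + 5 NA18507 replicates -> 21 + 10 = 31 same-sample pairs
    add("NA12878", "WES", "r1-1-1", "NA12878-E1")
    add("NA12878", "WES", "r1-1-2", "NA12878-E1")
    add("NA12878", "WES", "r2-1-1", "NA12878-E2")
    add("NA12878", "WES", "r3-1-1", "NA12878-E1")
    add("NA12878", "WES", "r3-2-1", "NA12878-E1")
    add("NA12878", "WES", "r4-1-1", "NA12878-E1")
    add("NA12878", "WES", "r4-2-1", "NA12878-E1")
    add("NA18507", "WES", "r2-1-2", "NA18507-E1")
    add("NA18507", "WES", "r2-1-3", "NA18507-E2")
    add("NA18507", "WES", "r3-1-2", "NA18507-E2")
    add("NA18507", "WES", "r4-1-2", "NA18507-E2")
    add("NA18507", "WES", "r4-2-2", "NA18507-E2")
    add("NA12891", "WES", "r3-1-3", "NA12891-E1")
    add("NA12891", "WES", "r4-1-3", "NA12891-E1")
    add("NA12891", "WES", "r4-2-3", "NA12891-E1")
    add("NA12892", "WES", "r3-1-4", "NA12892-E1")
    add("NA12892", "WES", "r4-1-4", "NA12892-E1")
    add("NA12892", "WES", "r4-2-4", "NA12892-E1")
    add("NA10080", "WES", "r2-1-4", "NA10080-E1")

    # WGS: 6 NA12878 + 3 NA18507 replicates -> 15 + 3 = 18 same-sample pairs
    add("NA12878", "WGS", "r1-1-1", "NA12878-W1")
    add("NA12878", "WGS", "r1-1-3", "NA12878-W1")
    add("NA12878", "WGS", "r2-1-1", "NA12878-W2")
    add("NA12878", "WGS", "r2-2-1", "NA12878-W2")
    add("NA12878", "WGS", "r3-1-1", "NA12878-W1")
    add("NA12878", "WGS", "r3-2-1", "NA12878-W1")
    add("NA18507", "WGS", "r2-1-3", "NA18507-W1")
    add("NA18507", "WGS", "r2-1-4", "NA18507-W2")
    add("NA18507", "WGS", "r3-1-3", "NA18507-W1")
    add("NA12891", "WGS", "r3-1-2", "NA12891-W1")
    add("NA12892", "WGS", "r3-1-4", "NA12892-W1")
    add("NA10080", "WGS", "r2-1-2", "NA10080-W1")
    return pd.DataFrame(rows)


@dataclass
class BatchEffectModel:
    """Additive comparison-kind effects on pairwise concordance.

    Generated concordances are ``base − Σ active deltas + noise``, clipped
    to [0, 1].  The default emulates the regime where replicate concordance
    sits near 0.99 and an inter-library comparison loses ~6e-4.
    """

    base: float = 0.99
    deltas: dict = field(
        default_factory=lambda: {"inter-library": 0.0006}
    )
    noise_sd: float = 0.0002
    design: pd.DataFrame = field(default_factory=reference_design)
    assay: str = "WGS"
    samples: tuple = ("NA12878", "NA18507")


def gen_replicate_family(
    template: Optional[BatchEffectModel] = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a replicate-design table and pairwise concordances drawn from
    the additive batch-effect model, ready for the concordance regression.

    The pairs table has columns truth_id, test_id, sample,
    comparison_kinds and concordance (one row per unordered pair; the
    metric is direction-symmetric)."""
    from .replicates import build_design

    template = template or BatchEffectModel()
    rng = np.random.default_rng(seed)
    design = template.design
    design = design[
        (design["assay"] == template.assay)
        & (design["sample"].isin(template.samples))
    ].reset_index(drop=True)
    cd = build_design(design)
    sample_of = dict(zip(design["replicate_id"], design["sample"]))
    rows = []
    for a, b, kinds, _label in cd.pairs:
        value = template.base - sum(
            template.deltas.get(k, 0.0) for k in kinds
        )
        value += rng.normal(0.0, template.noise_sd)
        rows.append(
            {
                "truth_id": a,
                "test_id": b,
                "sample": sample_of[a],
                "comparison_kinds": ",".join(sorted(kinds)),
                "concordance": float(np.clip(value, 0.0, 1.0)),
            }
        )
    return design, pd.DataFrame(rows)
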