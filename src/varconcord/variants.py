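"""Core variant-callset data model.

The unit of every downstream comparison is the normalized bi-allelic
:class:`Variant` — multi-allelic records are decomposed into one record per
alternate allele, alleles are made parsimonious and indels left-aligned, and
callsets are then joined on strict variant equality
(chromosome, position, reference allele, alternate allele).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "VariantClass",
    "GenotypeClass",
    "FilterStatus",
    "Variant",
    "GenotypeCall",
    "Callset",
    "NormalizationError",
    "normalize_alleles",
    "left_align",
    "decompose_genotypes",
    "chrom_sort_key",
]


class VariantClass(str, Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    OTHER = "OTHER"


class GenotypeClass(str, Enum):
    HOMREF = "HOMREF"
    HET = "HET"
    HOMALT = "HOMALT"
    NOCALL = "NOCALL"


class FilterStatus(str, Enum):
    PASS = "PASS"
    FILTERED = "FILTERED"


class NormalizationError(ValueError):
    """Raised when alleles cannot be normalized against the given context."""


_CHROM_RE = re.compile(r"^(chr)?(\d+|X|Y|M|MT)$", re.IGNORECASE)

_SPECIAL_CHROM_RANK = {"X": 23, "Y": 24, "M": 25, "MT": 25}


def chrom_sort_key(chrom: str) -> tuple:
    """Sort key giving the natural order chr1..chr22, chrX, chrY, chrM,
    with unknown contigs lexicographic after."""
    m = _CHROM_RE.match(chrom)
    if m:
        body = m.group(2).upper()
        rank = _SPECIAL_CHROM_RANK.get(body) or int(body)
        return (0, rank, "")
    return (1, 0, chrom)


@dataclass(frozen=True, order=False)
class Variant:
    """A normalized bi-allelic variant: the strict-equality join key.

    ``pos`` is the 1-based position of the first reference base.  Exactly one
    alternate allele by construction; multi-allelic sites must be decomposed
    before a Variant is built.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele in {self.chrom}:{self.pos} {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos} ({self.ref})")

    @property
    def vclass(self) -> VariantClass:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantClass.SNV
        if len(self.ref) != len(self.alt) and min(len(self.ref), len(self.alt)) == 1:
            return VariantClass.INDEL
        return VariantClass.OTHER

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass
class GenotypeCall:
    """One genotype observation of a bi-allelic variant.

    ``gclass`` reflects the copy count of *this record's* alt allele only
    (2 copies → HOMALT, 1 → HET, 0 → HOMREF, missing → NOCALL); copies of
    any sibling alt allele from a decomposed multi-allelic site count as
    non-alt here.
    """

    variant: Variant
    gclass: GenotypeClass
    filter_status: FilterStatus = FilterStatus.PASS
    annotations: dict = field(default_factory=dict)

    @property
    def is_nonref(self) -> bool:
        return self.gclass in (GenotypeClass.HET, GenotypeClass.HOMALT)


class Callset:
    """One replicate's calls plus provenance, keyed by Variant.

    ``exhaustive`` declares that the callset reports *every* variant inside
    its target intervals (true for arrays, validated panels and
    high-confidence reference sets); it governs whether test-only calls count
    against precision when this callset is the truth side.
    """

    def __init__(
        self,
        replicate_id: str,
        sample: str,
        calls: Iterable[GenotypeCall] = (),
        provenance: Optional[Mapping[str, str]] = None,
        exhaustive: bool = False,
    ) -> None:
        self.replicate_id = replicate_id
        self.sample = sample
        self.provenance = dict(provenance or {})
        self.exhaustive = exhaustive
        self._calls: dict[tuple, GenotypeCall] = {}
        for call in calls:
            self.add(call)

    def add(self, call: GenotypeCall) -> None:
        key = call.variant.key
        if key in self._calls:
            raise ValueError(f"duplicate call for {call.variant}")
        self._calls[key] = call

    def __len__(self) -> int:
        return len(self._calls)

    def __contains__(self, variant: Variant) -> bool:
        return variant.key in self._calls

    def __iter__(self) -> Iterator[GenotypeCall]:
        return iter(sorted(self._calls.values(), key=lambda c: c.variant.sort_key()))

    def get(self, variant: Variant) -> Optional[GenotypeCall]:
        return self._calls.get(variant.key)

    def keys(self) -> set:
        return set(self._calls)

    def variants(self) -> list[Variant]:
        return [c.variant for c in self]

    def restrict(self, intervals: "IntervalSet") -> "Callset":
        """Retain calls whose 1-based position falls inside the intervals."""
        kept = [
            c
            for c in self._calls.values()
            if intervals.contains(c.variant.chrom, c.variant.pos - 1)
        ]
        return Callset(
            self.replicate_id,
            self.sample,
            kept,
            provenance=self.provenance,
            exhaustive=self.exhaustive,
        )

    def subset(self, vclass: VariantClass) -> "Callset":
        kept = [c for c in self._calls.values() if c.variant.vclass is vclass]
        return Callset(
            self.replicate_id,
            self.sample,
            kept,
            provenance=self.provenance,
            exhaustive=self.exhaustive,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Callset({self.replicate_id!r}, sample={self.sample!r}, n={len(self)})"


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Make an allele pair parsimonious without reference context.

    Trims the shared suffix, then the shared prefix while both alleles keep
    at least one base, advancing ``pos`` accordingly.  Left-alignment against
    reference sequence is a separate step (:func:`left_align`).
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def left_align(
    variant: Variant, context: str, context_start: int
) -> Variant:
    """Left-align and trim a variant against a reference subsequence.

    ``context`` is reference sequence whose first base sits at 1-based
    position ``context_start`` on ``variant.chrom``.  The returned variant is
    parsimonious, left-shifted to its fixpoint, and haplotype-preserving.
    SNVs come back unchanged.  Raises :class:`NormalizationError` when the
    reference allele disagrees with the context or the window is too small
    to prove the fixpoint.
    """
    context = context.upper()
    pos, ref, alt = variant.pos, variant.ref.upper(), variant.alt.upper()

    offset = pos - context_start
    if offset < 0 or offset + len(ref) > len(context):
        raise NormalizationError(
            f"context window [{context_start},{context_start + len(context)}) "
            f"does not cover {variant}"
        )
    if context[offset : offset + len(ref)] != ref:
        raise NormalizationError(
            f"reference allele {ref} at {variant.chrom}:{pos} does not match "
            f"context {context[offset:offset + len(ref)]}"
        )

    # Right-trim shared suffix bases, extending left through the reference
    # whenever an allele would empty out; this walks indels leftward through
    # tandem repeats to their leftmost representation.
    while ref[-1] == alt[-1]:
        if len(ref) == 1 or len(alt) == 1:
            if pos <= context_start:
                raise NormalizationError(
                    f"left-alignment of {variant} ran out of context; "
                    f"supply a window extending further left"
                )
            pos -= 1
            base = context[pos - context_start]
            ref, alt = base + ref[:-1], base + alt[:-1]
        else:
            ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return Variant(variant.chrom, pos, ref, alt)


def _is_symbolic(alt: str) -> bool:
    return alt.startswith("<") or alt == "*" or "[" in alt or "]" in alt


def decompose_genotypes(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    gt_alleles: Sequence[Optional[int]],
    filter_status: FilterStatus = FilterStatus.PASS,
    annotations: Optional[Mapping[str, float]] = None,
) -> list[GenotypeCall]:
    """Decompose a (possibly multi-allelic) site into bi-allelic calls.

    One output per alternate allele, in alt order.  Each record's genotype
    class comes from the copy count of its own alt allele; missing alleles
    (including half-calls like ``0/.``) propagate as NOCALL.  Haploid
    genotypes map alt→HOMALT, non-alt→HOMREF.  Symbolic alleles are dropped
    with a logged count.
    """
    annotations = dict(annotations or {})
    calls: list[GenotypeCall] = []
    n_symbolic = 0
    for i, alt in enumerate(alts, start=1):
        if _is_symbolic(alt):
            n_symbolic += 1
            continue
        if any(a is None for a in gt_alleles) or len(gt_alleles) == 0:
            gclass = GenotypeClass.NOCALL
        else:
            copies = sum(1 for a in gt_alleles if a == i)
            if len(gt_alleles) == 1:  # haploid (sex chromosomes)
                gclass = GenotypeClass.HOMALT if copies == 1 else GenotypeClass.HOMREF
            elif copies >= 2:
                gclass = GenotypeClass.HOMALT
            elif copies == 1:
                gclass = GenotypeClass.HET
            else:
                gclass = GenotypeClass.HOMREF
        npos, nref, nalt = normalize_alleles(pos, ref, alt)
        calls.append(
            GenotypeCall(
                Variant(chrom, npos, nref, nalt),
                gclass,
                filter_status,
                dict(annotations),
            )
        )
    if n_symbolic:
        logger.info(
            "excluded %d symbolic allele(s) at %s:%d", n_symbolic, chrom, pos
        )
    return calls
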