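"""Reading and writing callsets as VCF, plus the replicate-design table."""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd
import pysam

from .variants import (
    Callset,
    FilterStatus,
    GenotypeCall,
    GenotypeClass,
    decompose_genotypes,
)

__all__ = ["read_vcf", "write_vcf", "read_design_table", "DESIGN_COLUMNS"]

# INFO/FORMAT annotations harvested when present on a record.
_ANNOTATION_KEYS = ("VQSLOD", "QD", "MQ", "DP", "STATUS")

DESIGN_COLUMNS = ["replicate_id", "sample", "library", "run", "machine", "mode", "assay"]


def _scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def read_vcf(
    path: str,
    sample: Optional[str] = None,
    replicate_id: Optional[str] = None,
    exhaustive: bool = False,
) -> Callset:
    """Read one sample's calls from a VCF v4.x file into a :class:`Callset`.

    Multi-allelic records are decomposed; FILTER values other than PASS or
    ``.`` mark the call FILTERED (``.`` counts as PASS because truth sets
    such as arrays and panels carry no filters).
    """
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    if sample is None:
        if len(samples) != 1:
            raise ValueError(
                f"{path} has {len(samples)} samples; specify one of {samples}"
            )
        sample = samples[0]
    if sample not in samples:
        raise ValueError(f"sample {sample!r} not in {path}; available: {samples}")

    calls: list[GenotypeCall] = []
    callset = Callset(
        replicate_id or sample, sample, provenance={}, exhaustive=exhaustive
    )
    for i, rec in enumerate(vf, start=1):
        try:
            filters = list(rec.filter.keys())
            if not filters or filters == ["PASS"]:
                fstatus = FilterStatus.PASS
            else:
                fstatus = FilterStatus.FILTERED
            annotations = {}
            for key in _ANNOTATION_KEYS:
                if key in rec.info:
                    val = _scalar(rec.info[key])
                    if val is not None:
                        annotations[key] = val
            fmt = rec.samples[sample]
            if "DP" in fmt and fmt["DP"] is not None and "DP" not in annotations:
                annotations["DP"] = fmt["DP"]
            gt = fmt.get("GT", (None,))
            if gt is None:
                gt = (None,)
            for call in decompose_genotypes(
                rec.chrom,
                rec.pos,
                rec.ref,
                rec.alts or (),
                gt,
                fstatus,
                annotations,
            ):
                callset.add(call)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed record #{i}: {exc}") from exc
    return callset


_GT_FOR_CLASS = {
    GenotypeClass.HOMREF: (0, 0),
    GenotypeClass.HET: (0, 1),
    GenotypeClass.HOMALT: (1, 1),
    GenotypeClass.NOCALL: (None, None),
}


def write_vcf(
    callset: Callset, path: str, contig_lengths: Optional[dict] = None
) -> None:
    """Write a callset as a sorted bi-allelic VCF v4.2 file."""
    header = pysam.VariantHeader()
    chroms: dict[str, int] = {}
    ann_keys: set[str] = set()
    for call in callset:
        v = call.variant
        chroms[v.chrom] = max(chroms.get(v.chrom, 0), v.pos + len(v.ref) + 1)
        ann_keys.update(
            k for k, x in call.annotations.items() if isinstance(x, (int, float))
        )
    for chrom in chroms:
        length = (contig_lengths or {}).get(chrom, max(chroms[chrom], 1_000_000))
        header.contigs.add(chrom, length=length)
    header.filters.add("FILTERED", None, None, "Flagged by the variant filter")
    for key in sorted(ann_keys):
        header.info.add(key, 1, "Float", f"{key} annotation")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(callset.sample)

    with pysam.VariantFile(path, "w", header=header) as out:
        for call in callset:
            v = call.variant
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                alleles=(v.ref, v.alt),
                filter="PASS" if call.filter_status is FilterStatus.PASS else "FILTERED",
            )
            for key in sorted(ann_keys & set(call.annotations)):
                rec.info[key] = float(call.annotations[key])
            rec.samples[callset.sample]["GT"] = _GT_FOR_CLASS[call.gclass]
            out.write(rec)


def read_design_table(path: str) -> pd.DataFrame:
    """Read the replicate-design TSV naming each replicate and its
    library/run/machine/mode/assay provenance."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design table {path} missing columns: {missing}")
    return df


def callset_from_design_row(row: pd.Series, calls=(), exhaustive=False) -> Callset:
    """Build an empty callset carrying the provenance of one design row."""
    return Callset(
        row["replicate_id"],
        row["sample"],
        calls,
        provenance={
            k: row[k] for k in ("library", "run", "machine", "mode", "assay")
        },
        exhaustive=exhaustive,
    )
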