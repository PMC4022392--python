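"""Variant model: classification, decomposition, normalization, VCF round-trip."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varconcord import (
    Callset,
    GenotypeClass,
    Variant,
    VariantClass,
    decompose_genotypes,
    left_align,
    normalize_alleles,
    read_vcf,
    write_vcf,
)
from varconcord.variants import FilterStatus, NormalizationError, chrom_sort_key

from .conftest import make_call, make_callset


@pytest.mark.parametrize(
    "ref,alt,vclass",
    [
        ("A", "G", VariantClass.SNV),
        ("A", "AT", VariantClass.INDEL),
        ("ATT", "A", VariantClass.INDEL),
        ("AT", "GC", VariantClass.OTHER),  # MNP
        ("AT", "GCC", VariantClass.OTHER),
    ],
)
def test_variant_classification(ref, alt, vclass):
    assert Variant("chr1", 10, ref, alt).vclass is vclass


def test_variant_rejects_degenerate_alleles():
    with pytest.raises(ValueError):
        Variant("chr1", 1, "A", "A")
    with pytest.raises(ValueError):
        Variant("chr1", 1, "", "G")


def test_chrom_natural_order():
    chroms = ["chrX", "chr2", "chr10", "chr1", "chrM", "weird", "chrY"]
    assert sorted(chroms, key=chrom_sort_key) == [
        "chr1",
        "chr2",
        "chr10",
        "chrX",
        "chrY",
        "chrM",
        "weird",
    ]


class TestDecompose:
    def test_biallelic_identity(self):
        calls = decompose_genotypes("chr1", 100, "A", ["G"], (0, 1))
        assert len(calls) == 1
        assert calls[0].variant == Variant("chr1", 100, "A", "G")
        assert calls[0].gclass is GenotypeClass.HET

    def test_het_on_two_alts_gives_two_hets(self):
        calls = decompose_genotypes("chr1", 100, "A", ["G", "T"], (1, 2))
        assert [(c.variant.alt, c.gclass) for c in calls] == [
            ("G", GenotypeClass.HET),
            ("T", GenotypeClass.HET),
        ]

    def test_homalt_on_first_alt_is_homref_for_second(self):
        calls = decompose_genotypes("chr1", 100, "A", ["G", "T"], (1, 1))
        assert [c.gclass for c in calls] == [
            GenotypeClass.HOMALT,
            GenotypeClass.HOMREF,
        ]

    def test_missing_genotype_propagates_to_all_records(self):
        calls = decompose_genotypes("chr1", 100, "A", ["G", "T"], (None, None))
        assert [c.gclass for c in calls] == [GenotypeClass.NOCALL] * 2

    def test_half_call_is_nocall(self):
        (call,) = decompose_genotypes("chr1", 100, "A", ["G"], (0, None))
        assert call.gclass is GenotypeClass.NOCALL

    @pytest.mark.parametrize(
        "gt,expected",
        [((1,), GenotypeClass.HOMALT), ((0,), GenotypeClass.HOMREF)],
    )
    def test_haploid_mapping(self, gt, expected):
        (call,) = decompose_genotypes("chrX", 100, "A", ["G"], gt)
        assert call.gclass is expected

    def test_symbolic_alleles_excluded_not_fatal(self):
        calls = decompose_genotypes("chr1", 100, "A", ["<DEL>", "G"], (1, 2))
        assert len(calls) == 1
        assert calls[0].variant.alt == "G"

    @given(
        n_alts=st.integers(1, 3),
        gt=st.tuples(st.integers(0, 3), st.integers(0, 3)),
    )
    @settings(max_examples=200, deadline=None)
    def test_decomposition_conserves_allele_evidence(self, n_alts, gt):
        # sum of per-record alt copies equals the original non-ref copy count
        gt = tuple(min(a, n_alts) for a in gt)
        alts = ["G", "T", "C"][:n_alts]
        calls = decompose_genotypes("chr1", 50, "A", alts, gt)
        copies = {GenotypeClass.HOMREF: 0, GenotypeClass.HET: 1, GenotypeClass.HOMALT: 2}
        total = sum(copies[c.gclass] for c in calls)
        assert total == sum(1 for a in gt if a != 0)


class TestNormalization:
    def test_parsimony_trims_suffix_then_prefix_with_anchor(self):
        assert normalize_alleles(100, "CTCC", "CCC") == (100, "CT", "C")
        assert normalize_alleles(100, "GCGCG", "GCG") == (100, "GCG", "G")

    def test_snv_unchanged(self):
        v = Variant("chr1", 100, "A", "G")
        assert left_align(v, "TTAGT", 98) == v

    def test_deletion_shifts_to_tract_left_end(self):
        # CACACA tract at 100..105; deleting the rightmost CA must move to
        # the leftmost representation anchored at 99.
        ctx, start = "TCACACAG", 99
        out = left_align(Variant("chr1", 103, "ACA", "A"), ctx, start)
        assert out == Variant("chr1", 99, "TCA", "T")

    def test_leftmost_insertion_unchanged_and_idempotent(self):
        ctx, start = "AGAAC", 99
        v = Variant("chr1", 100, "G", "GTC")
        assert left_align(v, ctx, start) == v

    def test_context_mismatch_raises(self):
        with pytest.raises(NormalizationError, match="does not match"):
            left_align(Variant("chr1", 100, "AC", "A"), "TGGGG", 99)

    def test_window_too_small_raises(self):
        # deletion in a poly-A tract starting exactly at the window edge
        with pytest.raises(NormalizationError, match="context"):
            left_align(Variant("chr1", 100, "AA", "A"), "AAAA", 100)


def _apply(ctx: str, start: int, v: Variant) -> str:
    off = v.pos - start
    return ctx[:off] + v.alt + ctx[off + len(v.ref) :]


def _brute_force_leftmost(ctx: str, start: int, v: Variant) -> Variant:
    """Enumerate every parsimonious representation in the window producing
    the same haplotype; return the leftmost."""
    target = _apply(ctx, start, v)
    best = None
    for off in range(len(ctx)):
        for rlen in range(1, len(ctx) - off + 1):
            ref = ctx[off : off + rlen]
            # alt must make ctx[:off] + alt + ctx[off+rlen:] == target
            alen = len(target) - (len(ctx) - rlen)
            if alen < 1:
                continue
            alt = target[off : off + alen]
            if ctx[:off] + alt + ctx[off + rlen :] != target or ref == alt:
                continue
            cand = Variant(v.chrom, start + off, ref, alt)
            p, r, a = normalize_alleles(cand.pos, cand.ref, cand.alt)
            cand = Variant(v.chrom, p, r, a)
            if best is None or (cand.pos, len(cand.ref)) < (best.pos, len(best.ref)):
                best = cand
    return best


@given(
    unit=st.text(alphabet="ACGT", min_size=1, max_size=3),
    n_repeats=st.integers(2, 5),
    offset=st.integers(0, 4),
    deletion=st.booleans(),
    seed=st.integers(0, 10_000),
)
@settings(max_examples=150, deadline=None)
def test_left_align_matches_brute_force_on_tandem_repeats(
    unit, n_repeats, offset, deletion, seed
):
    """Haplotype-preserving leftmost representation on randomized repeats."""
    rng = np.random.default_rng(seed)
    flank = "".join(rng.choice(list("ACGT"), 8))
    tract = unit * n_repeats
    ctx = flank + tract + flank
    start = 1000
    # place an indel of one repeat unit somewhere inside the tract
    anchor_off = len(flank) + min(offset, len(tract) - len(unit)) - 1
    anchor_off = max(anchor_off, 0)
    anchor = ctx[anchor_off]
    if deletion:
        v = Variant(
            "chr1",
            start + anchor_off,
            anchor + ctx[anchor_off + 1 : anchor_off + 1 + len(unit)],
            anchor,
        )
    else:
        v = Variant("chr1", start + anchor_off, anchor, anchor + unit)

    out = left_align(v, ctx, start)
    assert _apply(ctx, start, out) == _apply(ctx, start, v)  # haplotype kept
    assert left_align(out, ctx, start) == out  # idempotent
    expected = _brute_force_leftmost(ctx, start, v)
    assert (out.pos, out.ref, out.alt) == (expected.pos, expected.ref, expected.alt)


class TestVcfRoundTrip:
    def test_roundtrip_preserves_core_fields(self, tmp_path):
        calls = [
            make_call(100, GenotypeClass.HET, "A", "G", VQSLOD=3.5),
            make_call(200, GenotypeClass.HOMALT, "C", "CAT"),
            make_call(300, GenotypeClass.HET, "TTG", "T", filtered=True),
            make_call(50, GenotypeClass.HET, "A", "T", chrom="chr2"),
        ]
        cs = make_callset(calls, replicate_id="S/r1-1-1", sample="S")
        path = str(tmp_path / "out.vcf")
        write_vcf(cs, path)
        back = read_vcf(path, "S")
        assert back.keys() == cs.keys()
        for call in cs:
            b = back.get(call.variant)
            assert b.gclass is call.gclass
            assert b.filter_status is call.filter_status
        assert back.get(calls[0].variant).annotations["VQSLOD"] == pytest.approx(3.5)

    def test_vqsr_tranche_filter_reads_as_filtered(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FILTER=<ID=VQSRTrancheSNP99.50to99.90,Description="tranche">\n'
            "##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\n"
            "chr1\t100\t.\tA\tG\t.\tVQSRTrancheSNP99.50to99.90\t.\tGT\t0/1\n"
            "chr1\t200\t.\tC\tT\t.\t.\t.\tGT\t0/1\n"
            "chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t1/1\n"
        )
        cs = read_vcf(str(path), "S")
        statuses = {c.variant.pos: c.filter_status for c in cs}
        assert statuses[100] is FilterStatus.FILTERED
        assert statuses[200] is FilterStatus.PASS  # "." treated as PASS
        assert statuses[300] is FilterStatus.PASS

    def test_multiallelic_record_is_decomposed_on_read(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\n"
            "chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t1/2\n"
        )
        cs = read_vcf(str(path), "S")
        assert {(c.variant.alt, c.gclass) for c in cs} == {
            ("G", GenotypeClass.HET),
            ("T", GenotypeClass.HET),
        }

    def test_missing_sample_error_names_available(self, tmp_path):
        path = tmp_path / "s.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA12878\n"
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(ValueError, match="NA12878"):
            read_vcf(str(path), "NA99999")


def test_callset_rejects_duplicate_keys():
    cs = make_callset([make_call(100)])
    with pytest.raises(ValueError, match="duplicate"):
        cs.add(make_call(100))


def test_restrict_half_open_boundary(chr1_universe):
    from varconcord import IntervalSet

    cs = make_callset([make_call(100), make_call(101)])
    kept = cs.restrict(IntervalSet([("chr1", 99, 100)]))
    assert [c.variant.pos for c in kept] == [100]
    assert cs.restrict(chr1_universe).keys() == cs.keys()
    assert len(cs.restrict(IntervalSet())) == 0
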