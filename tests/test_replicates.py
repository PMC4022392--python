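"""Replicate uniformity, comparison-kind classification, and the
concordance regression."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from varconcord import (
    BatchEffectModel,
    GenotypeClass,
    IntervalSet,
    VariantClass,
    build_design,
    gen_replicate_family,
    reference_design,
    regress_concordance,
    uniformity,
)
from varconcord.replicates import COMPARISON_KINDS, derive_kinds

from .conftest import make_call, make_callset


def sets_to_callsets(site_sets, sample="S"):
    out = []
    for i, sites in enumerate(site_sets):
        out.append(
            make_callset([make_call(p) for p in sites], f"{sample}/r{i}", sample)
        )
    return out


class TestUniformity:
    def test_identical_replicates_all_at_k_n(self):
        css = sets_to_callsets([{1, 2, 3}] * 4)
        table = uniformity(css)
        assert table.pct[4] == 100.0
        assert all(v == 0 for v in table.n_private.values())

    def test_worked_three_replicate_example(self):
        # replicates carry {A,B,C}, {A,B}, {A} -> thirds at k=3,2,1
        css = sets_to_callsets([{1, 2, 3}, {1, 2}, {1}])
        table = uniformity(css)
        assert table.pct[3] == pytest.approx(100 / 3)
        assert table.pct[2] == pytest.approx(100 / 3)
        assert table.pct[1] == pytest.approx(100 / 3)
        assert table.n_private == {"S/r0": 1, "S/r1": 0, "S/r2": 0}

    def test_restriction_drops_sites(self):
        css = sets_to_callsets([{1, 2, 3}, {1, 2}, {1}])
        table = uniformity(css, restriction=IntervalSet([("chr1", 0, 2)]))
        # site 3 (private to the first replicate) excluded
        assert table.n_union == 2
        assert table.pct[3] == 50.0
        assert table.pct[2] == 50.0

    def test_percentages_sum_to_100(self, rng):
        sets = [
            set(rng.choice(200, rng.integers(20, 100), replace=False))
            for _ in range(5)
        ]
        table = uniformity(sets_to_callsets(sets))
        assert sum(table.pct.values()) == pytest.approx(100.0)
        assert sum(table.counts.values()) == table.n_union

    def test_filtered_calls_still_count_as_called(self):
        a = make_callset([make_call(1, filtered=True)], "A", "S")
        b = make_callset([make_call(1)], "B", "S")
        table = uniformity([a, b])
        assert table.pct[2] == 100.0

    def test_vtype_partition(self):
        a = make_callset([make_call(1), make_call(2, ref="A", alt="AT")], "A", "S")
        b = make_callset([make_call(1)], "B", "S")
        snv = uniformity([a, b], VariantClass.SNV)
        indel = uniformity([a, b], VariantClass.INDEL)
        assert snv.n_union == 1 and snv.pct[2] == 100.0
        assert indel.n_union == 1 and indel.pct[1] == 100.0

    def test_mixed_samples_rejected(self):
        a = make_callset([make_call(1)], "A", "NA12878")
        b = make_callset([make_call(1)], "B", "NA18507")
        with pytest.raises(ValueError, match="mixed"):
            uniformity([a, b])


class TestKindDerivation:
    @staticmethod
    def prov(run, machine, mode="high-throughput", library="L1"):
        return {"run": run, "machine": machine, "mode": mode, "library": library}

    def test_same_run_same_machine_is_intra_run(self):
        kinds = derive_kinds(self.prov("r2", "1"), self.prov("r2", "1"))
        assert kinds == {"intra-run"}

    def test_same_machine_different_run_is_inter_run(self):
        kinds = derive_kinds(self.prov("r2", "1"), self.prov("r3", "1"))
        assert kinds == {"inter-run"}

    def test_different_machine_is_inter_machine(self):
        kinds = derive_kinds(self.prov("r3", "1"), self.prov("r3", "2"))
        assert kinds == {"inter-machine"}

    def test_composed_kinds_get_other_label(self):
        a = self.prov("r3", "1", library="L1")
        b = self.prov("r3", "2", library="L2")
        kinds = derive_kinds(a, b)
        assert kinds == {"inter-machine", "inter-library"}

    def test_mode_difference_is_inter_mode(self):
        kinds = derive_kinds(
            self.prov("r3", "1"), self.prov("r4", "1", mode="rapid")
        )
        assert "inter-mode" in kinds


# Published pair classifications: (sample, assay, rep_a, rep_b, expected kind)
REFERENCE_PAIR_TABLE = [
    ("NA12878", "WES", "r1-1-1", "r1-1-2", "intra-run"),
    ("NA18507", "WES", "r2-1-2", "r2-1-3", "intra-run"),
    ("NA18507", "WES", "r2-1-2", "r3-1-2", "inter-run"),
    ("NA18507", "WES", "r2-1-3", "r3-1-2", "inter-run"),
    ("NA12878", "WES", "r1-1-1", "r2-1-1", "inter-run"),
    ("NA12878", "WES", "r1-1-1", "r3-1-1", "inter-run"),
    ("NA12878", "WES", "r2-1-1", "r3-1-1", "inter-run"),
    ("NA12878", "WES", "r3-1-1", "r3-2-1", "inter-machine"),
    ("NA12878", "WES", "r4-1-1", "r4-2-1", "inter-machine"),
    ("NA18507", "WES", "r4-1-2", "r4-2-2", "inter-machine"),
    ("NA12878", "WGS", "r1-1-1", "r1-1-3", "intra-run"),
    ("NA18507", "WGS", "r2-1-3", "r2-1-4", "intra-run"),
    ("NA18507", "WGS", "r2-1-3", "r3-1-3", "inter-run"),
    ("NA18507", "WGS", "r2-1-4", "r3-1-3", "inter-run"),
    ("NA12878", "WGS", "r1-1-1", "r2-1-1", "inter-run"),
    ("NA12878", "WGS", "r1-1-1", "r3-1-1", "inter-run"),
    ("NA12878", "WGS", "r2-1-1", "r3-1-1", "inter-run"),
    ("NA12878", "WGS", "r2-2-1", "r3-2-1", "inter-run"),
    ("NA12878", "WGS", "r3-1-1", "r3-2-1", "inter-machine"),
    ("NA12878", "WGS", "r2-1-1", "r2-2-1", "inter-machine"),
]


class TestBuildDesign:
    def test_reference_design_reproduces_published_pair_kinds(self):
        design = reference_design()
        for assay in ("WES", "WGS"):
            cd = build_design(design[design.assay == assay])
            kinds_of = {
                frozenset((a, b)): kinds for a, b, kinds, _ in cd.pairs
            }
            for sample, asy, ra, rb, kind in REFERENCE_PAIR_TABLE:
                if asy != assay:
                    continue
                key = frozenset((f"{sample}/{ra}", f"{sample}/{rb}"))
                assert key in kinds_of, (sample, ra, rb)
                assert kind in kinds_of[key], (sample, ra, rb, kinds_of[key])

    def test_reference_design_pair_counts_match_study(self):
        design = reference_design()
        both = design[design["sample"].isin(["NA12878", "NA18507"])]
        wes = build_design(both[both.assay == "WES"])
        wgs = build_design(both[both.assay == "WGS"])
        assert len(wes.pairs) == 31
        assert len(wgs.pairs) == 18

    def test_inter_mode_pairs_only_in_wes(self):
        design = reference_design()
        for assay, expect_any in (("WES", True), ("WGS", False)):
            cd = build_design(design[design.assay == assay])
            has_mode = any("inter-mode" in kinds for _, _, kinds, _ in cd.pairs)
            assert has_mode is expect_any

    def test_missing_provenance_field_names_row(self):
        design = reference_design().copy()
        design.loc[0, "library"] = ""
        with pytest.raises(ValueError, match=design.loc[0, "replicate_id"]):
            build_design(design)

    def test_cross_sample_and_cross_assay_pairs_excluded(self):
        cd = build_design(reference_design())
        for a, b, _, _ in cd.pairs:
            assert a.split("/")[0] == b.split("/")[0]


class TestRegression:
    def test_zero_noise_recovers_injected_effect_exactly(self):
        template = BatchEffectModel(
            deltas={"inter-library": 0.0006}, noise_sd=0.0
        )
        design, pairs = gen_replicate_family(template, seed=0)
        result = regress_concordance(build_design(design), pairs)
        assert result.coefficients["inter-library"] == pytest.approx(
            -0.0006, abs=1e-12
        )
        # kinds with no signal have (numerically) zero coefficients
        for kind in result.kinds_tested:
            if kind != "inter-library" and kind in result.coefficients:
                assert abs(result.coefficients[kind]) < 1e-10

    def test_noisy_recovery_within_three_se(self):
        template = BatchEffectModel(
            deltas={"inter-library": 0.0006}, noise_sd=0.0002
        )
        design, pairs = gen_replicate_family(template, seed=42)
        result = regress_concordance(build_design(design), pairs)
        coef = result.coefficients["inter-library"]
        se = result.std_errors["inter-library"]
        assert abs(coef - (-0.0006)) < 3 * se

    def test_all_identical_concordances_give_zero_coefficients(self):
        template = BatchEffectModel(deltas={}, noise_sd=0.0)
        design, pairs = gen_replicate_family(template, seed=1)
        result = regress_concordance(build_design(design), pairs)
        for kind in result.kinds_tested:
            if kind in result.coefficients:
                assert result.coefficients[kind] == pytest.approx(0.0, abs=1e-12)

    def test_constant_kind_dropped(self):
        design, pairs = gen_replicate_family(BatchEffectModel(), seed=2)
        result = regress_concordance(build_design(design), pairs)
        # no WGS rapid-run replicates exist, so inter-mode never varies
        assert "inter-mode" in result.kinds_dropped
        assert result.alpha_perkind == pytest.approx(
            0.05 / len(result.kinds_tested)
        )

    def test_strong_effect_is_flagged_significant(self):
        template = BatchEffectModel(
            deltas={"inter-library": 0.005}, noise_sd=0.0002
        )
        design, pairs = gen_replicate_family(template, seed=3)
        result = regress_concordance(build_design(design), pairs)
        assert "inter-library" in result.significant_kinds
        assert result.overall_pvalue < 0.05
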