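import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sirnakit import (
    PairAssayRecord,
    PairCall,
    ValidationError,
    analyze_screen,
    classify_pair,
    ddct_fold_change,
    de_filter,
    gen_assay_tables,
    knockdown_efficiency,
    screen_pair,
    screen_report,
    validation_candidates,
)


def ct_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "replicate", "ct"])


class TestDdctFoldChange:
    def base_table(self):
        return ct_table(
            [
                ("0C", "GAPDH", 1, 20.0),
                ("0C", "TGT", 1, 24.0),
                ("S1", "GAPDH", 1, 20.0),
                ("S1", "TGT", 1, 25.0),
            ]
        )

    def test_worked_example_half(self):
        fc = ddct_fold_change(self.base_table(), "TGT")
        assert fc.loc["S1"] == pytest.approx(0.5)  # ddCt = 1
        assert fc.loc["0C"] == pytest.approx(1.0)

    def test_twofold_up(self):
        t = self.base_table()
        t.loc[t["sample_id"].eq("S1") & t["gene_id"].eq("TGT"), "ct"] = 23.0
        assert ddct_fold_change(t, "TGT").loc["S1"] == pytest.approx(2.0)  # ddCt = -1

    def test_replicates_averaged_before_differencing(self):
        t = ct_table(
            [
                ("0C", "GAPDH", 1, 20.0), ("0C", "GAPDH", 2, 20.0),
                ("0C", "TGT", 1, 23.0), ("0C", "TGT", 2, 25.0),  # mean 24
                ("S1", "GAPDH", 1, 20.0),
                ("S1", "TGT", 1, 25.0),
            ]
        )
        assert ddct_fold_change(t, "TGT").loc["S1"] == pytest.approx(0.5)

    def test_missing_reference_or_control_identified(self):
        t = self.base_table()
        with pytest.raises(ValidationError, match="ACTB"):
            ddct_fold_change(t, "TGT", reference_gene="ACTB")
        with pytest.raises(ValidationError, match="0X"):
            ddct_fold_change(t, "TGT", control_sample="0X")
        gap = t[~(t["sample_id"].eq("S1") & t["gene_id"].eq("GAPDH"))]
        with pytest.raises(ValidationError, match="S1"):
            ddct_fold_change(gap, "TGT")

    @given(st.floats(-3, 3))
    def test_invariant_to_constant_ct_shift_per_sample(self, shift):
        t = self.base_table()
        shifted = t.copy()
        shifted.loc[shifted["sample_id"] == "S1", "ct"] += shift
        base = ddct_fold_change(t, "TGT").loc["S1"]
        assert ddct_fold_change(shifted, "TGT").loc["S1"] == pytest.approx(base)


class TestKnockdownEfficiency:
    def test_definition_and_clipping(self):
        assert knockdown_efficiency(0.4) == pytest.approx(60.0)
        assert knockdown_efficiency(1.0) == 0.0
        assert knockdown_efficiency(1.3) == 0.0  # up-regulation clips to 0


def record(kd_match=90.0, kd_mismatch=5.0, vm=1.0, vmm=1.0, screen_pass=None):
    return PairAssayRecord(
        gene_id="G", kd_match=kd_match, kd_mismatch=kd_mismatch,
        viability_match=vm, viability_mismatch=vmm, screen_pass=screen_pass,
    )


class TestScreenPair:
    @pytest.mark.parametrize(
        "kd_m, kd_mm, expected",
        [
            (70, 10, True),   # 70 > 60 and gap 60 >= 50
            (65, 30, False),  # gap only 35
            (60, 0, False),   # criterion (i) is strict
            (60.5, 10.5, True),
            (90, 40.5, False),  # gap 49.5
            (90, 40, True),     # gap exactly 50 passes
        ],
    )
    def test_criteria_boundaries(self, kd_m, kd_mm, expected):
        assert screen_pair(record(kd_m, kd_mm)) is expected


class TestClassifyPair:
    def test_essential_pattern(self):
        # Match kills the cells, Mismatch leaves them intact
        assert classify_pair(record(vm=0.75, vmm=1.0, screen_pass=True)) is PairCall.ESSENTIAL

    def test_off_target_pattern(self):
        # viability drops under the Mismatch control too
        r = record(vm=0.78, vmm=0.78, screen_pass=True)
        assert classify_pair(r) is PairCall.OFF_TARGET_CONFOUNDED

    def test_non_essential_and_invalid(self):
        assert classify_pair(record(vm=0.95, vmm=0.98, screen_pass=True)) is PairCall.NON_ESSENTIAL
        assert classify_pair(record(screen_pass=False)) is PairCall.INVALID_PAIR

    @given(st.floats(0.0, 1.5), st.floats(0.0, 1.5))
    def test_monotone_in_match_viability(self, vm, vmm):
        """Lowering Match viability can only move a call toward essential."""
        order = {
            PairCall.NON_ESSENTIAL: 0,
            PairCall.ESSENTIAL: 1,
            PairCall.OFF_TARGET_CONFOUNDED: 1,  # unaffected by vm
        }
        hi = classify_pair(record(vm=vm, vmm=vmm, screen_pass=True))
        lo = classify_pair(record(vm=max(0.0, vm - 0.3), vmm=vmm, screen_pass=True))
        assert order[lo] >= order[hi] or lo is hi


class TestDeFilter:
    def exp_table(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "fpkm_s1", "fpkm_s2", "fpkm_s3",
                           "fold_change", "p_value"]
        )

    @pytest.mark.parametrize(
        "fc, p, kept",
        [
            (1.6, 0.005, True),
            (1.6, 0.02, False),   # p not below 0.01
            (0.5, 0.001, True),   # 2-fold down-regulation
            (1.5, 0.001, False),  # threshold is strict
            (1.0 / 1.5, 0.001, False),
            (1.4, 0.001, False),
        ],
    )
    def test_two_sided_thresholds(self, fc, p, kept):
        t = self.exp_table([("G1", 10, 10, 10, fc, p)])
        assert (len(de_filter(t)) == 1) is kept

    def test_relaxing_thresholds_grows_survivors(self):
        rng = np.random.default_rng(5)
        t = self.exp_table(
            [(f"G{i}", 10, 10, 10, fc, p)
             for i, (fc, p) in enumerate(zip(rng.uniform(0.2, 3.0, 50),
                                             rng.uniform(0, 0.05, 50)))]
        )
        strict = set(de_filter(t, fc_min=1.5, p_max=0.01)["gene_id"])
        loose_fc = set(de_filter(t, fc_min=1.2, p_max=0.01)["gene_id"])
        loose_p = set(de_filter(t, fc_min=1.5, p_max=0.03)["gene_id"])
        assert strict <= loose_fc and strict <= loose_p

    def test_fdr_option_is_stricter_on_uniform_p(self):
        rng = np.random.default_rng(6)
        t = self.exp_table(
            [(f"G{i}", 10, 10, 10, 2.0, p) for i, p in enumerate(rng.uniform(0, 1, 100))]
        )
        assert len(de_filter(t, fdr=True)) <= len(de_filter(t))


class TestValidationCandidates:
    def exp_table(self, triples):
        return pd.DataFrame(
            [(f"G{i}", a, b, c, 2.0, 0.001) for i, (a, b, c) in enumerate(triples)],
            columns=["gene_id", "fpkm_s1", "fpkm_s2", "fpkm_s3",
                     "fold_change", "p_value"],
        )

    def test_strictly_above_in_every_sample(self):
        t = self.exp_table([(25, 30, 21), (25, 19, 40), (20, 30, 30)])
        kept = validation_candidates(t)
        assert list(kept["gene_id"]) == ["G0"]  # G1 dips below, G2 sits at 20

    def test_seeded_subsample_is_stable(self):
        t = self.exp_table([(30 + i, 40, 50) for i in range(20)])
        a = validation_candidates(t, k=6, seed=123)
        b = validation_candidates(t, k=6, seed=123)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 6


class TestAnalyzeScreen:
    def test_planted_patterns_recovered_end_to_end(self):
        ct, viab, manifest = gen_assay_tables(seed=101)
        records = analyze_screen(ct, viab)
        calls = {r.gene_id: str(r.call) for r in records}
        assert calls == manifest["expected_calls"]
        report = screen_report(records)
        assert report.attrs["call_counts"]["essential"] == 1
        assert report.attrs["call_counts"]["off_target_confounded"] == 1

    def test_empty_screen_reports_zero_counts(self):
        ct, viab, _ = gen_assay_tables(plan=[], seed=0)
        report = screen_report(analyze_screen(ct, viab))
        assert len(report) == 0
        assert all(v == 0 for v in report.attrs["call_counts"].values())

    def test_record_invariants_enforced(self):
        with pytest.raises(ValidationError):
            record(vm=-0.1)
        with pytest.raises(ValidationError):
            record(kd_match=101.0)
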