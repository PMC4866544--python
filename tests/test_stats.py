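import math

import numpy as np
import pandas as pd
import pytest

from mpratag.stats import (
    AnalysisError,
    ActivityTestResult,
    COMPARISON_DA,
    COMPARISON_NC,
    NONPOSITIVE,
    QC_EXCLUDED,
    ZERO_DENOM,
    ReplicateLogRatio,
    analyze_dataset,
    bh_adjust,
    cell_line_correlations,
    classify_variants,
    negcontrol_log_ratio,
    one_sample_t_test,
    qc_flag_replicates,
    replicate_log_ratio,
    signed_fold_change,
)


class TestReplicateLogRatio:
    def test_perfect_symmetry_is_zero(self):
        r = replicate_log_ratio(110, 10, 110, 10, 50, 50)
        assert r.valid and r.value == 0.0

    def test_derived_threefold(self):
        # oracle: ln((300/100)/(40/40)) = ln 3
        r = replicate_log_ratio(310, 10, 110, 10, 40, 40)
        assert r.value == pytest.approx(math.log(3), abs=1e-12)
        assert r.value == pytest.approx(1.0986, abs=1e-4)

    def test_nonpositive_after_subtraction(self):
        r = replicate_log_ratio(15, 20, 110, 10, 40, 40)
        assert not r.valid
        assert r.invalid_reason == NONPOSITIVE
        assert math.isnan(r.value)

    def test_zero_rna_is_nonpositive(self):
        r = replicate_log_ratio(20, 20, 110, 10, 40, 40)
        assert r.invalid_reason == NONPOSITIVE

    def test_zero_denominator(self):
        r = replicate_log_ratio(110, 10, 110, 10, 40, 0)
        assert r.invalid_reason == ZERO_DENOM
        r = replicate_log_ratio(110, 10, 110, 10, 0, 40)
        assert r.invalid_reason == ZERO_DENOM

    def test_antisymmetry_example(self):
        a = replicate_log_ratio(310, 10, 110, 10, 40, 30)
        b = replicate_log_ratio(110, 10, 310, 10, 30, 40)
        assert a.value == pytest.approx(-b.value, abs=1e-15)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            replicate_log_ratio(-1, 0, 10, 0, 5, 5)

    def test_oracle_equivalence_random(self):
        # independent direct-arithmetic oracle on random count sextuples
        rng = np.random.default_rng(11)
        for _ in range(2000):
            d_p, d_m, a_p, a_m = rng.integers(0, 500, size=4)
            d_dna, a_dna = rng.integers(1, 500, size=2)
            r = replicate_log_ratio(d_p, d_m, a_p, a_m, d_dna, a_dna)
            if d_p - d_m > 0 and a_p - a_m > 0:
                expected = (
                    math.log(d_p - d_m)
                    - math.log(a_p - a_m)
                    - math.log(d_dna)
                    + math.log(a_dna)
                )
                assert r.value == pytest.approx(expected, abs=1e-12)
            else:
                assert not r.valid


class TestNegcontrolLogRatio:
    def test_equal_counts_zero(self):
        r = negcontrol_log_ratio(110, 10, 110, 10, 30, 30)
        assert r.value == 0.0
        assert r.comparison == COMPARISON_NC

    def test_twofold(self):
        r = negcontrol_log_ratio(210, 10, 110, 10, 30, 30)
        assert r.value == pytest.approx(math.log(2), abs=1e-12)
        assert r.value == pytest.approx(0.6931, abs=1e-4)

    def test_zero_negcontrol_dna(self):
        r = negcontrol_log_ratio(210, 10, 110, 10, 30, 0)
        assert r.invalid_reason == ZERO_DENOM


class TestQcFlagReplicates:
    def test_identical_counts_none_excluded(self):
        vals = {r: 0.01 for r in range(1, 11)}
        assert all(qc_flag_replicates(vals, vals).values())

    def test_high_rtminus_outlier_excluded(self):
        # oracle: others' median = 0.001, MAD = 0 -> 0.05 > 0.001
        rtminus = {r: 0.001 for r in range(1, 10)}
        rtminus[10] = 0.05
        rtplus = {r: 0.01 for r in range(1, 11)}
        valid = qc_flag_replicates(rtplus, rtminus)
        assert valid[10] is False
        assert all(valid[r] for r in range(1, 10))

    def test_low_rtplus_outlier_excluded(self):
        rtplus = {r: 0.02 for r in range(1, 10)}
        rtplus[10] = 0.0001
        rtminus = {r: 0.001 for r in range(1, 11)}
        valid = qc_flag_replicates(rtplus, rtminus)
        assert valid[10] is False

    def test_mad_threshold_arithmetic(self):
        # others for r=6: (10,11,12,13,14)/1000; median 0.012,
        # MAD = 1.4826*0.001; threshold 0.012 + 3*0.0014826 = 0.0164478
        base = {1: 0.010, 2: 0.011, 3: 0.012, 4: 0.013, 5: 0.014}
        rtplus = {r: 0.1 for r in range(1, 7)}
        valid = qc_flag_replicates(rtplus, {**base, 6: 0.0165})
        assert valid[6] is False
        valid = qc_flag_replicates(rtplus, {**base, 6: 0.0164})
        assert valid[6] is True

    def test_external_exclusion_unconditional(self):
        vals = {r: 0.01 for r in range(1, 11)}
        valid = qc_flag_replicates(vals, vals, external_exclusions=[7])
        assert valid[7] is False
        assert sum(valid.values()) == 9

    def test_few_replicates_warns_no_flagging(self):
        rtminus = {1: 0.001, 2: 0.001, 3: 0.9}
        rtplus = {1: 0.01, 2: 0.01, 3: 0.01}
        with pytest.warns(UserWarning, match="3 replicates"):
            valid = qc_flag_replicates(rtplus, rtminus)
        assert all(valid.values())


class TestOneSampleTTest:
    def test_closed_form_two_values(self):
        # df=1: p = 2*(0.5 - atan(t)/pi); t = 2.0 for values (0.5, 1.5)
        out = one_sample_t_test([0.5, 1.5])
        assert out.t == pytest.approx(2.0, abs=1e-12)
        assert out.df == 1
        assert out.p == pytest.approx(2 * (0.5 - math.atan(2.0) / math.pi), abs=1e-12)
        assert out.p == pytest.approx(0.2952, abs=1e-4)

    def test_all_zero_p_one(self):
        out = one_sample_t_test([0.0, 0.0, 0.0])
        assert out.p == 1.0

    def test_sign_flip_symmetry(self):
        values = [0.3, -0.1, 0.8, 0.2]
        a = one_sample_t_test(values)
        b = one_sample_t_test([-v for v in values])
        assert a.t == pytest.approx(-b.t, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-15)

    def test_degenerate_nonzero_mean(self):
        out = one_sample_t_test([0.5, 0.5, 0.5])
        assert out.p == 0.0
        assert out.note == "degenerate"

    def test_untestable_single_value(self):
        out = one_sample_t_test([0.5])
        assert out.note == "untestable"
        assert math.isnan(out.p)

    def test_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        values = rng.normal(0.2, 1.0, size=9)
        out = one_sample_t_test(values)
        ref = sps.ttest_1samp(values, 0.0)
        assert out.t == pytest.approx(ref.statistic, rel=1e-12)
        assert out.p == pytest.approx(ref.pvalue, rel=1e-12)


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_example(self):
        # hand oracle: q_i = min_{j>=i} m*p_j/j
        # (0.01, 0.02, 0.04) -> (min(.03,.03,.04), min(.03,.04), .04)
        q = bh_adjust([0.01, 0.02, 0.04])
        assert q == pytest.approx([0.03, 0.03, 0.04], abs=1e-12)

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])
        with pytest.raises(ValueError):
            bh_adjust([])

    def test_order_preserving(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=40)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)


class TestSignedFoldChange:
    def test_zero_is_plus_one(self):
        assert signed_fold_change(0.0) == 1.0

    def test_reduction_to_38_percent(self):
        # -1/0.38 = -2.6316
        assert signed_fold_change(math.log(0.38)) == pytest.approx(
            -1 / 0.38, rel=1e-12
        )
        assert signed_fold_change(math.log(0.38)) == pytest.approx(-2.63, abs=5e-3)

    def test_identity_on_positive_ratio(self):
        assert signed_fold_change(math.log(1.8)) == pytest.approx(1.8, rel=1e-12)

    def test_no_values_in_open_unit_interval(self):
        for m in np.linspace(-3, 3, 61):
            assert abs(signed_fold_change(m)) >= 1.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            signed_fold_change(math.nan)


class TestCellLineCorrelations:
    def test_identical_columns(self):
        df = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
        out = cell_line_correlations(df)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_negated_column(self):
        df = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [-1.0, -2.0, -3.0]})
        out = cell_line_correlations(df)
        assert out.loc[0, "r"] == pytest.approx(-1.0)

    def test_direct_formula_oracle(self):
        # (1,2,3) vs (1,2,4): r = 3/sqrt(2 * 14/3)
        df = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 4.0]})
        out = cell_line_correlations(df)
        expected = 3 / math.sqrt(2 * 14 / 3)
        assert out.loc[0, "r"] == pytest.approx(expected, rel=1e-12)
        assert out.loc[0, "r"] == pytest.approx(0.9820, abs=1e-4)

    def test_insufficient_overlap_flagged(self):
        df = pd.DataFrame({"A": [1.0, 2.0, np.nan], "B": [1.0, np.nan, 3.0]})
        out = cell_line_correlations(df)
        assert math.isnan(out.loc[0, "r"])
        assert out.loc[0, "note"] == "insufficient_overlap"

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({"A": [1.0, 1.0, 1.0], "B": [1.0, 2.0, 3.0]})
        out = cell_line_correlations(df)
        assert out.loc[0, "note"] == "zero_variance"


def _result(variant_id, cell_line, comparison, mean, significant):
    return ActivityTestResult(
        variant_id=variant_id,
        cell_line=cell_line,
        comparison=comparison,
        n_valid_replicates=10,
        mean_log_ratio=mean,
        t_statistic=3.0 if significant else 0.5,
        degrees_of_freedom=9,
        p_value=0.001 if significant else 0.5,
        q_value=0.01 if significant else 0.6,
        significant=significant,
        signed_fold_change=signed_fold_change(mean),
    )


class TestClassifyVariants:
    def test_enhancer_in_all_three_cell_lines(self):
        results = [
            _result("v1|ancestral", cl, COMPARISON_NC, 0.9, True)
            for cl in ("CL1", "CL2", "CL3")
        ] + [_result("v1", cl, COMPARISON_DA, 0.1, False) for cl in ("CL1", "CL2", "CL3")]
        out = classify_variants(results).set_index("variant_id")
        assert out.loc["v1", "n_cell_lines_enhancer"] == 3
        assert out.loc["v1", "n_cell_lines_repressor"] == 0

    def test_single_repressor_call(self):
        results = [
            _result("v2|derived", "CL1", COMPARISON_NC, -0.8, True),
            _result("v2|ancestral", "CL1", COMPARISON_NC, -0.1, False),
            _result("v2", "CL1", COMPARISON_DA, -0.2, False),
        ]
        out = classify_variants(results).set_index("variant_id")
        assert out.loc["v2", "n_cell_lines_repressor"] == 1
        assert out.loc["v2", "n_cell_lines_enhancer"] == 0

    def test_no_significant_calls(self):
        results = [
            _result("v3", "CL1", COMPARISON_DA, 0.1, False),
            _result("v3|ancestral", "CL1", COMPARISON_NC, 0.1, False),
        ]
        out = classify_variants(results).set_index("variant_id")
        assert (out.loc["v3"] == 0).all()

    def test_allelic_direction_split(self):
        results = [
            _result("v4", "CL1", COMPARISON_DA, 0.5, True),
            _result("v4", "CL2", COMPARISON_DA, -0.5, True),
            _result("v4", "CL3", COMPARISON_DA, 0.5, False),
        ]
        out = classify_variants(results).set_index("variant_id")
        assert out.loc["v4", "n_cell_lines_allelic_significant"] == 2
        assert out.loc["v4", "n_cell_lines_derived_up"] == 1
        assert out.loc["v4", "n_cell_lines_derived_down"] == 1


def _counts_frame(constructs, cell_lines=("CL1",), replicates=6, base=500):
    """Noise-free construct count table: every construct identical."""
    rows = []
    for cl in cell_lines:
        for rep in range(1, replicates + 1):
            for c in constructs:
                for assay, n in (("RTplus", base), ("RTminus", base // 10), ("DNA", base)):
                    rows.append(
                        {
                            "cell_line": cl,
                            "replicate": rep,
                            "assay": assay,
                            "construct_id": c.construct_id,
                            "count": n,
                        }
                    )
    return pd.DataFrame(rows)


class TestAnalyzeDataset:
    def test_missing_assay_named_error(self, small_constructs):
        df = _counts_frame(small_constructs)
        df = df[~((df.replicate == 3) & (df.assay == "RTminus"))]
        with pytest.raises(AnalysisError, match="RTminus.*replicate 3"):
            analyze_dataset(df, small_constructs)

    def test_flat_counts_all_null(self, small_constructs):
        df = _counts_frame(small_constructs)
        res = analyze_dataset(df, small_constructs)
        assert (res.results_da["mean_log_ratio"] == 0.0).all()
        assert not res.results_da["significant"].any()
        # identical replicate values -> degenerate t-test with p = 1
        assert (res.results_da["p"] == 1.0).all()
        assert len(res.results_da) == 3  # 3 variants x 1 cell line
        assert len(res.results_nc) == 6  # 6 allele constructs

    def test_zero_valid_replicates_is_untestable(self, small_constructs):
        df = _counts_frame(small_constructs)
        # zero out one variant's derived DNA everywhere -> zero_denominator
        cid = "chr10:118707481G>C|derived"
        df.loc[(df.construct_id == cid) & (df.assay == "DNA"), "count"] = 0
        res = analyze_dataset(df, small_constructs)
        row = res.results_da[res.results_da.variant_id == "chr10:118707481G>C"].iloc[0]
        assert row["note"] == "untestable"
        assert row["n_valid"] == 0
        assert any("untestable" in m for m in res.messages)

    def test_external_exclusions_drop_replicates(self, small_constructs):
        df = _counts_frame(small_constructs)
        res = analyze_dataset(
            df, small_constructs, external_exclusions=[("CL1", 2, None)]
        )
        rr = res.replicate_ratios
        excluded = rr[(rr.replicate == 2) & (rr.comparison == COMPARISON_DA)]
        assert (excluded.invalid_reason == QC_EXCLUDED).all()
        assert (res.results_da["n_valid"] == 5).all()

    def test_bh_family_modes(self, small_constructs):
        df = _counts_frame(small_constructs)
        for mode in ("separate", "combined"):
            res = analyze_dataset(df, small_constructs, bh_family_mode=mode)
            assert len(res.results_da) == 3
        with pytest.raises(ValueError):
            analyze_dataset(df, small_constructs, bh_family_mode="bogus")

    def test_replicate_log_ratio_invariants(self, small_constructs):
        df = _counts_frame(small_constructs)
        res = analyze_dataset(df, small_constructs)
        rr = res.replicate_ratios
        assert (rr.valid == np.isfinite(rr.value)).all()
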