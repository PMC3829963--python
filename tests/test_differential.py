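"""log2 fold change, classification threshold, estimator comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isomirseq.differential import (
    DifferentialError,
    classify,
    compare_estimators,
    differential_table,
    log2fc,
)

rpm = st.floats(min_value=0.01, max_value=1e6, allow_nan=False)


def expr_frame(data, library_id):
    rows = []
    for mid, (dom, total) in data.items():
        rows.append(
            {"mature_id": mid, "library_id": library_id, "dominant_count": dom,
             "sum_count": total, "n_isomirs": 1 + (total > dom),
             "dominant_rpm": dom, "sum_rpm": total}
        )
    return pd.DataFrame(rows)


class TestLog2FC:
    def test_fourfold_is_two(self):
        assert log2fc(400, 100, 0) == pytest.approx(2.0)

    def test_identity_is_zero(self):
        for pc in (0, 0.5, 2):
            assert log2fc(123.4, 123.4, pc) == pytest.approx(0.0)

    def test_pseudocount_with_zero_control(self):
        assert log2fc(400, 0, 0.5) == pytest.approx(math.log2(400.5 / 0.5))
        assert log2fc(400, 0, 0.5) == pytest.approx(9.64566, abs=1e-4)

    def test_zero_without_pseudocount_raises(self):
        with pytest.raises(DifferentialError):
            log2fc(0, 0, 0)

    @settings(max_examples=200, derandomize=True)
    @given(a=rpm, b=rpm, pc=st.floats(min_value=0, max_value=10))
    def test_antisymmetry(self, a, b, pc):
        assert log2fc(a, b, pc) == pytest.approx(-log2fc(b, a, pc), rel=1e-9, abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(b=rpm, a1=rpm, a2=rpm)
    def test_strictly_monotone_in_case(self, b, a1, a2):
        lo, hi = sorted((a1, a2))
        if lo == hi:
            return
        assert log2fc(lo, b, 0) < log2fc(hi, b, 0)


class TestClassify:
    def test_above_threshold_up(self):
        assert classify(2.1) == "up"

    def test_below_negative_threshold_down(self):
        assert classify(-2.1) == "down"

    def test_exactly_at_threshold_unchanged(self):
        assert classify(2.0) == "unchanged"
        assert classify(-2.0) == "unchanged"

    def test_alternative_twofold_threshold(self):
        assert classify(1.5, threshold=1.0) == "up"
        assert classify(1.5, threshold=2.0) == "unchanged"


class TestDifferentialTable:
    def test_single_isomir_divergence_zero(self):
        case = expr_frame({"m1": (40, 40)}, "case")
        control = expr_frame({"m1": (10, 10)}, "control")
        out = differential_table(case, control)
        assert out["estimator_divergence"].iloc[0] == pytest.approx(0.0)
        assert out["log2fc_sum"].iloc[0] == pytest.approx(2.0)

    def test_swapping_conditions_negates_fold_changes(self):
        case = expr_frame({"m1": (40, 80), "m2": (5, 10)}, "case")
        control = expr_frame({"m1": (10, 20), "m2": (50, 100)}, "control")
        fwd = differential_table(case, control).set_index("mature_id")
        rev = differential_table(control, case).set_index("mature_id")
        for mid in ("m1", "m2"):
            assert fwd.loc[mid, "log2fc_sum"] == pytest.approx(
                -rev.loc[mid, "log2fc_sum"]
            )
            assert fwd.loc[mid, "log2fc_dominant"] == pytest.approx(
                -rev.loc[mid, "log2fc_dominant"]
            )

    def test_detected_one_side_uses_pseudocount(self):
        case = expr_frame({"m1": (40, 40)}, "case")
        control = expr_frame({}, "control")
        out = differential_table(case, control)
        assert out["log2fc_sum"].iloc[0] == pytest.approx(math.log2(40.5 / 0.5))
        assert out["status"].iloc[0] == "up"

    def test_undetected_in_both_listed_not_zero_filled(self):
        case = expr_frame({"m1": (40, 40)}, "case")
        control = expr_frame({"m1": (30, 30)}, "control")
        out = differential_table(case, control, all_matures=["m1", "m2"])
        row = out.set_index("mature_id").loc["m2"]
        assert row["status"] == "undetected"
        assert np.isnan(row["log2fc_sum"])

    def test_status_follows_configured_estimator(self):
        case = expr_frame({"m1": (100, 400)}, "case")
        control = expr_frame({"m1": (80, 90)}, "control")
        by_sum = differential_table(case, control, estimator="sum")
        by_dom = differential_table(case, control, estimator="dominant")
        assert by_sum["status"].iloc[0] == "up"
        assert by_dom["status"].iloc[0] == "unchanged"


class TestCompareEstimators:
    def test_report_sorted_and_ranked(self):
        case = expr_frame(
            {"m1": (90, 90), "m2": (4, 8), "m3": (300, 600)}, "case"
        )
        control = expr_frame(
            {"m1": (10, 10), "m2": (40, 80), "m3": (200, 210)}, "control"
        )
        rep = compare_estimators(differential_table(case, control), top_n=5)
        comp = rep["comparison"]
        assert comp["log2fc_sum"].abs().is_monotonic_decreasing
        assert rep["top_up"]["mature_id"].tolist() == ["m1"]
        assert rep["top_down"]["mature_id"].tolist() == ["m2"]
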