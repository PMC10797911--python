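"""Concordance statistics against brute-force oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihcmil import (
    agreement_report,
    bland_altman,
    classify_marker,
    double_expressor,
    icc_two_way_absolute,
    pearson_with_ci,
    sens_spec,
)

from _oracles import (
    bland_altman_by_hand,
    icc21_anova,
    pearson_formula,
    sens_spec_counts,
)


class TestPearson:
    def test_perfect_and_inverse_correlation(self):
        x = [1.0, 2.0, 3.0]
        r, _, _ = pearson_with_ci(x, x, n_boot=50, seed=0)
        assert r == pytest.approx(1.0)
        r, _, _ = pearson_with_ci(x, [3.0, 2.0, 1.0], n_boot=50, seed=0)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 50)
        y = 0.8 * x + rng.normal(0, 20, 50)
        r, _, _ = pearson_with_ci(x, y, n_boot=10, seed=0)
        assert r == pytest.approx(pearson_formula(x, y), abs=1e-12)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, 40)
        y = x + rng.normal(0, 15, 40)
        r, lo, hi = pearson_with_ci(x, y, n_boot=1000, seed=5)
        assert lo <= r <= hi

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_ci([1, 1, 1], [1, 2, 3])

    def test_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 100, 30)
        y = x + rng.normal(0, 10, 30)
        r1, _, _ = pearson_with_ci(x, y, n_boot=10, seed=0)
        r2, _, _ = pearson_with_ci(2.5 * x + 7, y, n_boot=10, seed=0)
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestICC:
    def test_identity_is_one(self):
        x = np.arange(10.0)
        icc, p = icc_two_way_absolute(x, x)
        assert icc == pytest.approx(1.0)
        assert p < 0.01

    def test_offset_penalized_unlike_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 100, 25)
        icc_same, _ = icc_two_way_absolute(x, x)
        icc_off, _ = icc_two_way_absolute(x, x + 20)
        assert icc_off < icc_same
        r, _, _ = pearson_with_ci(x, x + 20, n_boot=10, seed=0)
        assert r == pytest.approx(1.0)

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 100, 20)
        y = x + rng.normal(0, 12, 20)
        icc, p = icc_two_way_absolute(x, y)
        icc_ref, p_ref = icc21_anova(x, y)
        assert icc == pytest.approx(icc_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-8)

    def test_reorder_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 100, 15)
        y = x + rng.normal(0, 8, 15)
        perm = rng.permutation(15)
        icc1, _ = icc_two_way_absolute(x, y)
        icc2, _ = icc_two_way_absolute(x[perm], y[perm])
        assert icc1 == pytest.approx(icc2, abs=1e-12)


class TestClinicalCalls:
    @pytest.mark.parametrize(
        "score,marker,expected",
        [
            (45, "c-MYC", True),
            (40, "c-MYC", False),
            (41, "c-MYC", True),
            (50, "BCL2", False),
            (51, "BCL2", True),
            (0, "BCL2", False),
            (100, "c-MYC", True),
        ],
    )
    def test_strict_threshold_calls(self, score, marker, expected):
        assert classify_marker(score, marker) is expected

    def test_unknown_marker_rejected(self):
        with pytest.raises(ValueError):
            classify_marker(50, "BCL6")

    @pytest.mark.parametrize(
        "myc,bcl2,expected",
        [(50, 60, True), (50, 50, False), (30, 90, False), (41, 51, True),
         (40, 90, False)],
    )
    def test_double_expressor_requires_both(self, myc, bcl2, expected):
        assert double_expressor(myc, bcl2) is expected

    def test_double_expressor_custom_thresholds(self):
        assert double_expressor(25, 35, thresholds=(20, 30)) is True
        assert double_expressor(25, 35, thresholds=(30, 30)) is False

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError):
            double_expressor(None, 50)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    myc=st.floats(0, 100, allow_nan=False),
    bcl2=st.floats(0, 100, allow_nan=False),
)
def test_calls_total_and_consistent(myc, bcl2):
    """classify_marker and double_expressor are pure and total on
    [0,100]^2, and DE is exactly the conjunction of the marker calls."""
    de = double_expressor(myc, bcl2)
    assert de == (classify_marker(myc, "c-MYC") and classify_marker(bcl2, "BCL2"))


class TestSensSpec:
    def test_perfect_and_inverted(self):
        truth = np.array([True, True, False, False, True])
        sens, spec, _, _ = sens_spec(truth, truth, n_boot=50, seed=0)
        assert (sens, spec) == (1.0, 1.0)
        sens, spec, _, _ = sens_spec(~truth, truth, n_boot=50, seed=0)
        assert (sens, spec) == (0.0, 0.0)

    def test_contingency_counts(self):
        truth = np.array([True] * 10 + [False] * 20)
        pred = np.array([True] * 7 + [False] * 3 + [False] * 18 + [True] * 2)
        sens, spec, sci, pci = sens_spec(pred, truth, n_boot=200, seed=1)
        assert sens == pytest.approx(0.7)
        assert spec == pytest.approx(0.9)
        ref = sens_spec_counts(pred, truth)
        assert (sens, spec) == pytest.approx(ref)
        assert sci.low <= sens <= sci.high
        assert pci.low <= spec <= pci.high

    def test_degenerate_truth_flagged(self):
        with pytest.raises(ValueError, match="sensitivity"):
            sens_spec([True, False], [False, False])
        with pytest.raises(ValueError, match="specificity"):
            sens_spec([True, False], [True, True])


class TestBlandAltman:
    def test_identical_scores_collapse(self):
        x = np.array([10.0, 30.0, 70.0])
        assert bland_altman(x, x) == pytest.approx((0.0, 0.0, 0.0))

    def test_hand_computed_alternating_differences(self):
        x = np.array([1.0, 0.0, 1.0, 0.0])
        y = np.zeros(4) + np.array([0.0, 1.0, 0.0, 1.0])
        md, lo, hi = bland_altman(x, y)
        assert md == pytest.approx(0.0)
        sd = np.sqrt(4.0 / 3.0)  # sample sd of [1,-1,1,-1]
        assert hi == pytest.approx(1.96 * sd, abs=1e-4)
        assert hi == pytest.approx(2.2632, abs=1e-3)
        assert lo == pytest.approx(-hi)

    def test_constant_offset(self):
        x = np.array([10.0, 20.0, 30.0])
        assert bland_altman(x + 5, x) == pytest.approx((5.0, 5.0, 5.0))

    def test_matches_oracle_and_ordering(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 100, 25)
        y = x + rng.normal(0, 9, 25)
        got = bland_altman(x, y)
        ref = bland_altman_by_hand(x, y)
        assert got == pytest.approx(ref, abs=1e-10)
        md, lo, hi = got
        assert lo <= md <= hi

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


def test_agreement_report_end_to_end():
    rng = np.random.default_rng(8)
    ref = rng.choice(np.arange(0, 101, 10), 60).astype(float)
    model = np.clip(ref + rng.normal(0, 8, 60), 0, 100)
    rep = agreement_report(ref, model, marker="c-MYC", n_boot=200, seed=0)
    d = rep.to_dict()
    assert -1 <= d["pearson_r"] <= 1
    assert -1 <= d["icc"] <= 1
    assert 0 <= d["sensitivity"] <= 1 and 0 <= d["specificity"] <= 1
    ba = d["bland_altman"]
    assert ba["loa_low"] <= ba["mean_diff"] <= ba["loa_high"]
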