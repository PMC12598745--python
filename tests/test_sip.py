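"""Isotopologue modeling, label-fraction estimation, aggregation and the
exact quantile test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from matsip import sip
from matsip.errors import (
    InsufficientDataError,
    InvalidValueError,
    NonIdentifiableError,
)
from matsip.isotope import natural_atom_fraction

X_NAT_C = natural_atom_fraction("C")


class TestPatterns:
    def test_single_carbon_natural(self):
        pattern = sip.natural_pattern(sip.ElementalComposition(n_c=1), length=2)
        assert pattern == pytest.approx([0.98894, 0.01106], abs=1e-5)

    def test_all_abundances_zero_is_delta(self):
        comp = sip.ElementalComposition(n_c=5, n_h=8, n_n=2, n_o=2)
        pattern = sip.natural_pattern(
            comp, 6, abundances={e: 0.0 for e in "CHNOS"})
        assert pattern == pytest.approx([1, 0, 0, 0, 0, 0])

    def test_patterns_normalized(self):
        comp = sip.ElementalComposition(n_c=60, n_h=95, n_n=16, n_o=18, n_s=1)
        for p in (X_NAT_C, 0.02, 0.3):
            assert sip.labeled_pattern(comp, p, 8).sum() == pytest.approx(
                1.0, abs=1e-12)

    def test_two_carbons_quarter_label(self):
        comp = sip.ElementalComposition(n_c=2)
        pattern = sip.labeled_pattern(
            comp, 0.25, 3, element="C")
        # pure binomial when only carbon present... other elements absent
        assert pattern == pytest.approx([0.5625, 0.375, 0.0625], abs=1e-12)

    def test_single_carbon_half_label(self):
        pattern = sip.labeled_pattern(sip.ElementalComposition(n_c=1), 0.5, 2)
        assert pattern == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_binomial_mean_for_pure_carbon(self):
        comp = sip.ElementalComposition(n_c=100)
        p = 0.0110566
        pattern = sip.labeled_pattern(comp, p, length=101)
        mean_index = float(np.sum(np.arange(101) * pattern))
        assert mean_index == pytest.approx(100 * p, abs=1e-9)

    def test_labeled_reduces_to_natural_at_natural_abundance(self):
        comp = sip.ElementalComposition(n_c=40, n_h=63, n_n=11, n_o=12)
        assert sip.labeled_pattern(comp, X_NAT_C, 8) == pytest.approx(
            sip.natural_pattern(comp, 8).tolist(), abs=1e-15)


class TestEstimateLabelFraction:
    comp = sip.ElementalComposition(n_c=50, n_h=79, n_n=14, n_o=15)

    def test_noiseless_inversion_natural(self):
        pattern = sip.labeled_pattern(self.comp, X_NAT_C, 8)
        p_hat, ratio = sip.estimate_label_fraction(pattern, self.comp)
        assert p_hat == pytest.approx(X_NAT_C, abs=1e-6)
        assert ratio == pytest.approx(p_hat / (1 - p_hat), rel=1e-12)

    def test_noisy_recovery_two_percent_label(self):
        rng = np.random.default_rng(42)
        pattern = sip.labeled_pattern(self.comp, 0.02, 8)
        noisy = pattern * rng.lognormal(0.0, 0.01, size=8)
        p_hat, _ = sip.estimate_label_fraction(noisy, self.comp)
        assert p_hat == pytest.approx(0.020, abs=0.001)

    def test_agrees_with_fine_grid_oracle(self):
        rng = np.random.default_rng(7)
        pattern = sip.labeled_pattern(self.comp, 0.015, 8)
        noisy = pattern * rng.lognormal(0.0, 0.01, size=8)
        p_hat, _ = sip.estimate_label_fraction(noisy, self.comp)
        grid = np.arange(max(p_hat - 2e-3, 0.0), p_hat + 2e-3, 1e-5)
        obs = noisy / noisy.sum()
        sse = [np.sum((obs - sip.labeled_pattern(self.comp, p, 8)) ** 2)
               for p in grid]
        assert abs(grid[int(np.argmin(sse))] - p_hat) < 2e-5

    def test_flat_pattern_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            sip.estimate_label_fraction(np.ones(8), self.comp)


class TestWeights:
    @pytest.mark.parametrize("intensity, expected",
                             [(250_000, 2), (0, 1), (100_000, 1),
                              (99_999, 1), (1_000_000, 10)])
    def test_weight_count(self, intensity, expected):
        assert sip.weight_count(intensity) == expected

    def test_mag_ratio_examples(self):
        assert sip.mag_ratio([0.013]) == 0.013
        assert sip.mag_ratio([1.0, 2.0, 9.0]) == 2.0  # median robustness
        # weights (3,1) expand to (1,1,1,2) → median 1
        assert sip.mag_ratio([1.0, 2.0], [3, 1]) == 1.0

    def test_mag_ratio_invariant_to_weight_doubling(self):
        rng = np.random.default_rng(0)
        ratios = rng.uniform(0.01, 0.02, 9)
        weights = rng.integers(1, 6, 9)
        assert sip.mag_ratio(ratios, weights) == pytest.approx(
            sip.mag_ratio(ratios, weights * 2), rel=1e-12)

    def test_weighted_median_matches_expansion(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            vals = rng.normal(size=7)
            w = rng.integers(1, 9, size=7)
            assert sip.mag_ratio(vals, w) == pytest.approx(
                float(np.median(np.repeat(vals, w))), rel=1e-12)

    def test_sample_ratio(self):
        assert sip.sample_ratio([0.010, 0.014], [3, 1]) == pytest.approx(0.011)
        assert sip.sample_ratio([0.02], [5.0]) == pytest.approx(0.02)
        assert sip.sample_ratio([1.0, 3.0], [1, 1]) == pytest.approx(2.0)
        with pytest.raises(InvalidValueError):
            sip.sample_ratio([1.0], [0.0])


class TestSharedPeptideFilter:
    def test_enumerated_survivors(self):
        rows = []
        presence = {
            "pepA": ["S1", "S2", "S3", "S4"],
            "pepB": ["S1", "S2", "S3"],
            "pepC": ["S1", "S2", "S3", "S4"],
            "pepD": ["S4"],
            "pepE": ["S1", "S3", "S4"],
            "pepF": ["S2", "S3", "S4"],
        }
        for pep, samples in presence.items():
            rows += [{"peptide_id": pep, "sample_id": s} for s in samples]
        out = sip.shared_peptide_filter(pd.DataFrame(rows))
        assert sorted(out["peptide_id"].unique()) == ["pepA", "pepC"]

    def test_needs_two_samples(self):
        df = pd.DataFrame([{"peptide_id": "p", "sample_id": "S1"}])
        with pytest.raises(InsufficientDataError):
            sip.shared_peptide_filter(df)


def enumeration_oracle(treatment, control, q):
    """Brute-force p-value: over all equally likely group assignments of
    the pooled values, the share with as many treatment observations above
    the pooled quantile cutoff as observed."""
    pooled = np.concatenate([treatment, control])
    big_n = len(pooled)
    cutoff = np.sort(pooled)[math.ceil(q * big_n) - 1]
    above = pooled > cutoff
    k_obs = int(above[: len(treatment)].sum())
    hits = total = 0
    for idx in itertools.combinations(range(big_n), len(treatment)):
        total += 1
        if int(above[list(idx)].sum()) >= k_obs:
            hits += 1
    return hits / total


class TestExactQuantileTest:
    def test_no_separation_p_one(self):
        # complete ties: nothing lies above the cutoff (r = 0)
        res = sip.exact_quantile_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.p_raw == 1.0
        # treatment entirely below control: k = 0
        res = sip.exact_quantile_test([1.0, 2.0], [3.0, 4.0])
        assert res.k == 0
        assert res.p_raw == 1.0

    def test_interleaved_ties_match_enumeration(self):
        vals = [1.0, 2.0, 3.0]
        res = sip.exact_quantile_test(vals, vals)
        assert res.p_raw == pytest.approx(
            enumeration_oracle(np.array(vals), np.array(vals), 0.5))

    def test_full_separation_three_vs_three(self):
        res = sip.exact_quantile_test([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert (res.k, res.r) == (3, 3)
        assert res.p_raw == pytest.approx(0.05)  # 1 / C(6,3)

    def test_full_separation_two_vs_two(self):
        res = sip.exact_quantile_test([3.0, 4.0], [1.0, 2.0])
        assert (res.k, res.r) == (2, 2)
        assert res.p_raw == pytest.approx(1 / 6)

    def test_weight_expansion(self):
        unweighted = sip.exact_quantile_test([3.0, 3.0, 4.0], [1.0, 2.0])
        weighted = sip.exact_quantile_test([3.0, 4.0], [1.0, 2.0],
                                           treatment_weights=[2, 1])
        assert weighted.p_raw == pytest.approx(unweighted.p_raw)

    @given(st.data())
    def test_matches_complete_enumeration(self, data):
        big_n = data.draw(st.integers(2, 12))
        n_t = data.draw(st.integers(1, big_n - 1))
        # mix of tied and distinct values
        values = data.draw(st.lists(
            st.integers(0, 4).map(float), min_size=big_n, max_size=big_n))
        q = data.draw(st.floats(0.1, 0.9))
        t, c = values[:n_t], values[n_t:]
        res = sip.exact_quantile_test(t, c, q)
        assert res.p_raw == pytest.approx(enumeration_oracle(t, c, q),
                                          abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            sip.exact_quantile_test([], [1.0])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert sip.bh_adjust([0.2]).tolist() == [0.2]

    def test_hand_example(self):
        assert sip.bh_adjust([0.01, 0.02, 0.03]).tolist() == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert sip.bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=25)
        adj = sip.bh_adjust(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(InvalidValueError):
            sip.bh_adjust([0.5, 1.2])


class TestSignificanceReport:
    def _result(self, p, mag="M"):
        return sip.QuantileTestResult(mag, "T", "C", 1, 2, p)

    def test_strict_alpha_boundary(self):
        report = sip.significance_report(
            [self._result(0.049), self._result(0.05)], alpha=0.05)
        # single-batch BH over two p-values: adjusted (0.05, 0.05)
        assert report["p_adj"].tolist() == pytest.approx([0.05, 0.05])
        assert report["significant"].tolist() == [False, False]

    def test_flagging_after_adjustment(self):
        report = sip.significance_report(
            [self._result(0.001), self._result(0.9)], alpha=0.05)
        assert report["significant"].tolist() == [True, False]


def test_labeled_mag_flagged_in_seeded_simulations():
    """A MAG stepped to 2% 13C is flagged against its control in nearly
    every simulation replicate."""
    comp_rng = np.random.default_rng(123)
    flagged = 0
    n_reps = 10
    for rep in range(n_reps):
        rng = np.random.default_rng(1000 + rep)
        rows = []
        for sample, p in (("trt", 0.02), ("ctl", X_NAT_C)):
            for i in range(25):
                n_c = int(comp_rng.integers(30, 90))
                comp = sip.ElementalComposition(n_c, int(1.6 * n_c),
                                                int(0.27 * n_c), int(0.3 * n_c))
                pattern = sip.labeled_pattern(comp, p, 8)
                noisy = pattern * rng.lognormal(0.0, 0.01, 8)
                p_hat, ratio = sip.estimate_label_fraction(noisy, comp)
                rows.append({"sample_id": sample, "peptide_id": f"pep{i}",
                             "mag_id": "M", "ratio": ratio, "weight_count": 1,
                             "summed_intensity": 1e5})
        tests = sip.run_quantile_tests(pd.DataFrame(rows), [("trt", "ctl")])
        flagged += int(tests["significant"].iloc[0])
    assert flagged >= int(0.9 * n_reps)
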