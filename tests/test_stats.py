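"""Windowed contrasts, Simes-Bonferroni correction, median split, effect sizes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erpsource import (
    compare_effect_sizes,
    max_window_amplitude,
    median_split,
    simes_bonferroni,
    window_contrast,
)

TIMES = np.arange(-200.0, 1000.0)


class TestWindowContrast:
    def test_identical_conditions_give_zero_effect(self, rng):
        erp = rng.standard_normal((8, TIMES.size))
        result = window_contrast(erp, erp.copy(), TIMES, (100.0, 300.0), electrode="Oz")
        assert result.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert result.standardized_difference == 0.0
        assert result.df == 7

    def test_standardized_difference_converges_to_delta_over_sigma(self, rng):
        # constant shift delta against per-subject baseline noise sigma
        delta, sigma, n = 0.6, 0.3, 800
        base = sigma * rng.standard_normal((n, TIMES.size))
        erpA = base + delta * (TIMES >= 0)[None, :]
        erpB = sigma * rng.standard_normal((n, TIMES.size))
        result = window_contrast(erpA, erpB, TIMES, (0.0, 1000.0))
        baseline_sd = np.concatenate(
            [erpA[:, TIMES < 0], erpB[:, TIMES < 0]]
        ).mean(axis=1).std(ddof=1)
        assert result.standardized_difference == pytest.approx(
            result.mean_difference / baseline_sd, rel=1e-9
        )
        assert result.standardized_difference == pytest.approx(delta / baseline_sd, rel=0.05)
        # consistency: the baseline-mean spread shrinks with the per-subject
        # averaging, so the ratio tracks delta / observed spread
        assert result.mean_difference == pytest.approx(delta, abs=0.02)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2"):
            window_contrast(np.ones((1, TIMES.size)), np.ones((1, TIMES.size)), TIMES, (0, 100))

    def test_window_outside_epoch_rejected(self, rng):
        erp = rng.standard_normal((4, TIMES.size))
        with pytest.raises(ValueError, match="window"):
            window_contrast(erp, erp, TIMES, (900.0, 1500.0))

    def test_type_one_error_calibrated_under_null(self, rng):
        # paired t on window means under no condition difference
        reps, n = 2000, 8
        rejections = 0
        for _ in range(reps):
            a = rng.standard_normal((n, 100))
            b = rng.standard_normal((n, 100))
            times = np.arange(-50.0, 50.0)
            result = window_contrast(a, b, times, (0.0, 50.0))
            rejections += result.p_value < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3.3 * np.sqrt(0.05 * 0.95 / reps)


class TestSimesBonferroni:
    def test_single_hypothesis_is_bonferroni(self):
        assert simes_bonferroni(np.array([0.04]), 0.05)[0]
        assert not simes_bonferroni(np.array([0.06]), 0.05)[0]

    def test_worked_example_all_rejected(self):
        # ordered p {0.01, 0.03, 0.04} vs thresholds {0.05/3, 0.10/3, 0.05}
        p = np.array([0.01, 0.03, 0.04])
        global_reject, rejections, adjusted = simes_bonferroni(p, 0.05)
        assert global_reject
        assert rejections.all()
        assert np.allclose(adjusted, [0.03, 0.04, 0.04])

    def test_large_p_values_never_rejected(self):
        global_reject, rejections, _ = simes_bonferroni(np.full(6, 0.9), 0.05)
        assert not global_reject
        assert not rejections.any()

    def test_agrees_with_statsmodels_oracle_for_small_m(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(99)
        for _ in range(1000):
            m = int(rng.integers(1, 6))
            p = np.round(rng.random(m), 3)
            _, rejections, adjusted = simes_bonferroni(p, 0.05)
            expected_rej, expected_adj = multipletests(p, 0.05, method="simes-hochberg")[:2]
            assert np.array_equal(rejections, expected_rej), p
            assert np.allclose(adjusted, expected_adj), p

    def test_global_test_matches_direct_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            m = int(rng.integers(1, 6))
            p = rng.random(m)
            expected = bool(
                np.any(np.sort(p) <= (np.arange(1, m + 1) * 0.05 / m))
            )
            assert simes_bonferroni(p, 0.05)[0] == expected

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=8).map(sorted),
    )
    @settings(deadline=None, max_examples=200)
    def test_adjusted_p_monotone_in_raw_p(self, p_sorted):
        _, _, adjusted = simes_bonferroni(np.array(p_sorted), 0.05)
        assert np.all(np.diff(adjusted) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            simes_bonferroni(np.array([0.5, 1.2]))
        with pytest.raises(ValueError):
            simes_bonferroni(np.array([np.nan]))


class TestMedianSplit:
    def test_fourteen_distinct_scores_split_seven_seven(self, rng):
        scores = {f"s{i:02d}": float(v) for i, v in enumerate(rng.permutation(14))}
        split = median_split(scores)
        assert len(split.low) == 7
        assert len(split.high) == 7
        assert max(scores[s] for s in split.low) <= split.split_value
        assert min(scores[s] for s in split.high) >= split.split_value

    def test_odd_n_assigns_median_subject_to_low(self):
        scores = {"a": 1.0, "b": 2.0, "c": 3.0}
        split = median_split(scores)
        assert "b" in split.low
        assert split.low == ("a", "b")
        assert split.high == ("c",)

    def test_ties_at_median_stable_across_input_order(self):
        scores = {"a": 1.0, "b": 2.0, "c": 2.0, "d": 2.0, "e": 3.0, "f": 4.0}
        reference = median_split(scores)
        for _ in range(5):
            items = list(scores.items())
            np.random.default_rng(_).shuffle(items)
            split = median_split(dict(items))
            assert split.low == reference.low
            assert split.high == reference.high

    def test_all_equal_scores_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            median_split({"a": 1.0, "b": 1.0})

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            median_split({"a": 1.0})


class TestMaxWindowAmplitude:
    def test_monotone_ramp_takes_last_in_window_sample(self):
        waveform = np.linspace(-1, 1, TIMES.size)
        value = max_window_amplitude(waveform, TIMES, (0.0, 200.0))
        in_window = (TIMES >= 0) & (TIMES < 200)
        assert value == waveform[in_window][-1]

    def test_single_impulse_returns_its_height(self):
        waveform = np.zeros(TIMES.size)
        waveform[np.searchsorted(TIMES, 120.0)] = 4.2
        assert max_window_amplitude(waveform, TIMES, (0.0, 200.0)) == 4.2

    def test_all_negative_waveform_keeps_sign(self):
        waveform = -2.0 - np.abs(np.sin(TIMES / 50.0))
        value = max_window_amplitude(waveform, TIMES, (0.0, 200.0))
        assert value < 0

    def test_window_is_half_open(self):
        waveform = np.zeros(TIMES.size)
        waveform[np.searchsorted(TIMES, 200.0)] = 9.9  # at the excluded edge
        assert max_window_amplitude(waveform, TIMES, (0.0, 200.0)) == 0.0


class TestCompareEffectSizes:
    def test_equal_effects_give_zero(self):
        Z, p = compare_effect_sizes(0.5, 20, 0.5, 30)
        assert Z == 0.0
        assert p == 1.0

    def test_antisymmetric_under_group_swap(self):
        Z1, _ = compare_effect_sizes(0.83, 7, 0.76, 7)
        Z2, _ = compare_effect_sizes(0.76, 7, 0.83, 7)
        assert Z1 == pytest.approx(-Z2)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_effect_sizes(0.5, 3, 0.5, 10)

    def test_d_conversion_preserves_ordering(self):
        Z_big, _ = compare_effect_sizes(1.2, 20, 0.2, 20, kind="d")
        assert Z_big > 0

    def test_type_one_error_calibrated_under_equal_true_effects(self):
        rng = np.random.default_rng(42)
        n, reps, rho = 50, 10_000, 0.3

        def draw_r(n, reps):
            x = rng.standard_normal((reps, n))
            e = rng.standard_normal((reps, n))
            y = rho * x + np.sqrt(1 - rho**2) * e
            xm = x - x.mean(axis=1, keepdims=True)
            ym = y - y.mean(axis=1, keepdims=True)
            return (xm * ym).sum(1) / np.sqrt((xm**2).sum(1) * (ym**2).sum(1))

        r1, r2 = draw_r(n, reps), draw_r(n, reps)
        se = np.sqrt(2.0 / (n - 3))
        Z = (np.arctanh(r1) - np.arctanh(r2)) / se
        # spot-check the vectorized null against the implementation
        Z0, _ = compare_effect_sizes(float(r1[0]), n, float(r2[0]), n)
        assert Z0 == pytest.approx(float(Z[0]), rel=1e-12)
        rate = np.mean(np.abs(Z) > 1.96)
        assert abs(rate - 0.05) < 3.3 * np.sqrt(0.05 * 0.95 / reps)
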