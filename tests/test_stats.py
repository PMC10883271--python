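"""Ensemble statistics: stoichiometry, tests from summaries, FWHM."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from telofibre import (
    DistributionCurve,
    ProportionCount,
    SummaryStats,
    classify_scores,
    fwhm,
    stoich_ratio,
    summarize_measurements,
    ttest_from_summary,
    two_prop_test,
)


class TestStoichiometry:
    @pytest.mark.parametrize(
        "dimer, array, expected",
        [
            (0.046, 0.012, 0.4),  # EM condition
            (0.2, 0.0337, 0.6),  # AUC condition
            (0.13, 0.0337, 0.4),  # gel-shift condition
            (1.0, 0.1, 1.0),
        ],
    )
    def test_printed_ratios(self, dimer, array, expected):
        assert stoich_ratio(dimer, array, repeats_per_array=10) == expected

    def test_rounding_is_half_up(self):
        assert stoich_ratio(0.35, 1.0, repeats_per_array=1) == 0.4
        assert stoich_ratio(0.25, 1.0, repeats_per_array=1) == 0.3

    @settings(derandomize=True, max_examples=50)
    @given(scale=st.floats(1e-3, 1e3), dimer=st.floats(1e-3, 10.0),
           array=st.floats(1e-3, 10.0))
    def test_homogeneous_in_concentration_units(self, scale, dimer, array):
        assert stoich_ratio(dimer, array) == stoich_ratio(scale * dimer, scale * array)

    def test_zero_array_concentration(self):
        with pytest.raises(ValueError):
            stoich_ratio(1.0, 0.0)


class TestTTestFromSummary:
    def test_identical_groups(self):
        a = SummaryStats(50, 10.0, 2.0)
        out = ttest_from_summary(a, a)
        assert out["t"] == 0.0 and out["p"] == pytest.approx(1.0)

    def test_internucleosome_distance_comparison(self):
        # EM inter-nucleosomal distances: (417, 7.4, 1.7) vs (285, 7.7, 1.5)
        out = ttest_from_summary(SummaryStats(417, 7.4, 1.7),
                                 SummaryStats(285, 7.7, 1.5))
        assert out["t"] == pytest.approx(-2.41, abs=0.01)
        assert out["df"] == 700
        assert out["p"] == pytest.approx(0.0164, abs=5e-4)

    def test_fibre_diameter_comparison(self):
        out = ttest_from_summary(SummaryStats(412, 15.3, 1.7),
                                 SummaryStats(268, 13.7, 1.0))
        assert out["t"] == pytest.approx(13.9, abs=0.15)
        assert out["p"] < 1e-30

    def test_zero_variance_convention(self):
        a = SummaryStats(10, 5.0, 0.0)
        assert ttest_from_summary(a, SummaryStats(12, 5.0, 0.0))["p"] == 1.0
        assert ttest_from_summary(a, SummaryStats(12, 6.0, 0.0))["p"] == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(
        na=st.integers(2, 500), nb=st.integers(2, 500),
        ma=st.floats(-50, 50), mb=st.floats(-50, 50),
        sa=st.floats(0.01, 20), sb=st.floats(0.01, 20),
        equal_var=st.booleans(),
    )
    def test_matches_reference_implementation(self, na, nb, ma, mb, sa, sb, equal_var):
        mine = ttest_from_summary(SummaryStats(na, ma, sa), SummaryStats(nb, mb, sb),
                                  equal_var=equal_var)
        t_ref, p_ref = sps.ttest_ind_from_stats(ma, sa, na, mb, sb, nb,
                                                equal_var=equal_var)
        assert mine["t"] == pytest.approx(t_ref, rel=1e-10, abs=1e-10)
        assert mine["p"] == pytest.approx(p_ref, rel=1e-10, abs=1e-12)


class TestTwoPropTest:
    def test_equal_proportions(self):
        out = two_prop_test(ProportionCount(30, 100), ProportionCount(30, 100))
        assert out["z"] == 0.0 and out["p"] == pytest.approx(1.0)

    def test_columnar_fraction_comparison(self):
        # columnar fibres: 82.5% with protein vs 42.5% with magnesium
        out = two_prop_test(ProportionCount(82.5, 100), ProportionCount(42.5, 100))
        assert out["z"] == pytest.approx(5.84, abs=0.01)
        assert out["p"] == pytest.approx(5.2e-9, rel=0.05)

    def test_extreme_difference(self):
        out = two_prop_test(ProportionCount(50, 100), ProportionCount(0, 100))
        assert out["p"] < 1e-12

    @settings(derandomize=True, max_examples=100)
    @given(
        xa=st.integers(1, 99), xb=st.integers(1, 99),
        na=st.integers(100, 500), nb=st.integers(100, 500),
    )
    def test_matches_statsmodels_reference(self, xa, xb, na, nb):
        from statsmodels.stats.proportion import proportions_ztest

        mine = two_prop_test(ProportionCount(xa, na), ProportionCount(xb, nb))
        z_ref, p_ref = proportions_ztest([xa, xb], [na, nb])
        assert mine["z"] == pytest.approx(z_ref, rel=1e-10, abs=1e-10)
        assert mine["p"] == pytest.approx(p_ref, rel=1e-10, abs=1e-12)


class TestClassifyScores:
    def test_single_class(self):
        assert classify_scores(["column"] * 100) == {"column": 100.0}

    def test_fractional_dual_label_particles(self):
        labels = [{"column"}] * 50 + [{"column", "globule"}] * 50
        out = classify_scores(labels)
        assert out["column"] == pytest.approx(75.0)
        assert out["globule"] == pytest.approx(25.0)

    def test_percentages_total_100(self, rng):
        classes = np.array(["globule", "ladder", "column"])
        labels = []
        for _ in range(300):
            k = rng.integers(1, 3)
            labels.append(set(rng.choice(classes, size=k, replace=False)))
        out = classify_scores(labels)
        assert sum(out.values()) == pytest.approx(100.0, abs=1e-9)

    def test_multinomial_frequencies_recovered(self, rng):
        p = {"globule": 0.5, "ladder": 0.2, "column": 0.3}
        labels = rng.choice(list(p), size=300, p=list(p.values()))
        out = classify_scores(list(labels))
        for cls, prob in p.items():
            se = 100 * np.sqrt(prob * (1 - prob) / 300)
            assert out[cls] == pytest.approx(100 * prob, abs=4 * se)

    def test_three_labels_rejected(self):
        with pytest.raises(ValueError):
            classify_scores([{"globule", "ladder", "column"}])


class TestSummarize:
    def test_plain_summary(self):
        out = summarize_measurements([7.0, 8.0, 9.0])
        assert (out.n, out.mean, out.sd) == (3, 8.0, 1.0)

    def test_outlier_cutoff(self):
        out = summarize_measurements([7.0, 8.0, 9.0, 40.0], outlier_cutoff=15.0)
        assert (out.n, out.mean, out.sd) == (3, 8.0, 1.0)

    def test_gaussian_sample_with_cutoff(self, rng):
        # emulates the inter-nucleosomal distance table, 15 nm cutoff
        values = rng.normal(7.4, 1.7, size=417)
        out = summarize_measurements(values, outlier_cutoff=15.0)
        assert out.mean == pytest.approx(7.4, abs=3 * 1.7 / np.sqrt(417))

    def test_too_few_survivors(self):
        with pytest.raises(ValueError):
            summarize_measurements([20.0, 21.0, 5.0], outlier_cutoff=15.0)


class TestFWHM:
    def test_triangle_geometry(self):
        grid = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        dens = np.array([0.0, 0.5, 1.0, 0.5, 0.0])
        out = fwhm(DistributionCurve(grid, dens))
        assert out["fwhm"] == pytest.approx(2.0)
        assert out["peak_position"] == 2.0

    def test_gaussian_analytic_width(self):
        s = np.arange(10.0, 50.0001, 0.05)
        sigma = 2.0
        curve = DistributionCurve(s, np.exp(-0.5 * ((s - 30.0) / sigma) ** 2))
        out = fwhm(curve)
        assert out["fwhm"] == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma,
                                            abs=0.01)

    def test_grid_refinement_converges(self):
        sigma, errs = 3.0, []
        for h in (0.5, 0.1, 0.02):
            s = np.arange(0.0, 60.0 + h / 2, h)
            curve = DistributionCurve(s, np.exp(-0.5 * ((s - 30.0) / sigma) ** 2))
            errs.append(abs(fwhm(curve)["fwhm"] - 2.3548 * sigma))
        assert errs[0] >= errs[-1]
        assert errs[-1] < 1e-3

    def test_outermost_vs_strict_crossings_on_bimodal_curve(self):
        s = np.linspace(0, 10, 1001)
        dens = np.exp(-0.5 * ((s - 4) / 0.5) ** 2) + 0.8 * np.exp(
            -0.5 * ((s - 6) / 0.5) ** 2
        )
        wide = fwhm(DistributionCurve(s, dens))["fwhm"]
        narrow = fwhm(DistributionCurve(s, dens), strict_single_peak=True)["fwhm"]
        assert wide > narrow

    def test_matches_piecewise_linear_root_oracle(self, rng):
        # independent crossing solver on the same discrete curve
        from scipy.interpolate import interp1d
        from scipy.optimize import brentq

        for _ in range(20):
            mu = rng.uniform(20, 40)
            sigma = rng.uniform(1.0, 5.0)
            s = np.arange(0.0, 60.001, 0.1)
            y = np.exp(-0.5 * ((s - mu) / sigma) ** 2)
            curve = DistributionCurve(s, y)
            half = y.max() / 2
            lin = interp1d(s, y - half)
            i_pk = np.argmax(y)
            left = brentq(lin, s[0], s[i_pk], xtol=1e-13)
            right = brentq(lin, s[i_pk], s[-1], xtol=1e-13)
            assert fwhm(curve)["fwhm"] == pytest.approx(right - left, abs=1e-9)

    def test_monotone_curve_rejected(self):
        s = np.linspace(0, 10, 50)
        with pytest.raises(ValueError, match="crossing"):
            fwhm(DistributionCurve(s, s))
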