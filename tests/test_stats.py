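"""Exact signed-rank test, fold-change construction and family-wise control."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cardiolipidomics import (ComparisonSpec, FamilyConfig, apply_family_control,
                              build_report, class_tests, clean_peaks,
                              compute_fold_changes, exact_signed_rank,
                              summarize_class)
from cardiolipidomics.presets import LIPID_CLASSES
from conftest import brute_force_signed_rank_p

KO_VS_WT = ComparisonSpec.from_label("KO_vs_WT")


def _profiles(rows):
    return pd.DataFrame(rows, columns=["species_id", "class", "genotype",
                                       "mean_concentration", "n_replicates"])


class TestExactSignedRank:
    @pytest.mark.parametrize("diffs, expected", [
        ([0.1, 0.2, 0.3, 0.4, 0.5], 0.0625),       # n=5, one sign
        ([0.3, 0.1, 0.2], 0.2500),                  # n=3, one sign
        ([0.1 * k for k in range(1, 10)], 0.0039),  # n=9, one sign: 2/512
        ([-1.0, 2.0, 3.0, 4.0, -5.0], 0.8125),      # n=5, lesser rank sum 6
        ([1.0, -2.0], 1.0000),                      # n=2, balanced
    ])
    def test_dyadic_reference_values(self, diffs, expected):
        res = exact_signed_rank(diffs)
        assert res.method == "exact"
        assert round(res.p_two_sided, 4) == expected

    def test_rank_sum_identity_without_zeros(self):
        d = [0.5, -1.2, 2.0, -0.1, 3.3, 1.1]
        res = exact_signed_rank(d)
        n = res.n_used
        assert res.w_plus + res.w_minus == n * (n + 1) / 2

    def test_zeros_dropped_before_ranking(self):
        assert exact_signed_rank([0.0, 1.0, 2.0]).n_used == 2

    @pytest.mark.parametrize("diffs", [[], [0.0, 0.0]])
    def test_untestable_reported_not_silent_one(self, diffs):
        res = exact_signed_rank(diffs)
        assert res.method == "untestable"
        assert math.isnan(res.p_two_sided)

    def test_ties_use_average_ranks_and_stay_exact(self):
        res = exact_signed_rank([1.0, 1.0, -1.0, 2.0])
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(
            brute_force_signed_rank_p([1.0, 1.0, -1.0, 2.0]))

    def test_seeded_random_cases_match_enumeration_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(1, 9))
            if rng.random() < 0.5:  # force ties via a coarse grid
                d = rng.choice([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0], size=n)
            else:
                d = rng.normal(0, 1, n)
            res = exact_signed_rank(d)
            assert res.p_two_sided == pytest.approx(
                brute_force_signed_rank_p(d), abs=1e-12)

    @given(st.lists(st.floats(min_value=-50, max_value=50,
                              allow_nan=False).filter(lambda x: abs(x) > 1e-6),
                    min_size=1, max_size=8))
    @settings(max_examples=120, derandomize=True, deadline=None)
    def test_property_matches_oracle(self, diffs):
        res = exact_signed_rank(diffs)
        assert res.p_two_sided == pytest.approx(
            brute_force_signed_rank_p(diffs), abs=1e-12)

    def test_min_likelihood_convention_is_valid_probability(self):
        d = [0.4, -0.2, 0.9, 1.5, -0.1]
        p = exact_signed_rank(d, p_convention="min_likelihood").p_two_sided
        assert 0.0 < p <= 1.0

    def test_large_n_normal_approximation_flagged_and_close_to_scipy(self):
        rng = np.random.default_rng(5)
        d = np.round(rng.normal(0.2, 1.0, 40), 1)
        d = d[d != 0]
        res = exact_signed_rank(d, exact_n_max=25)
        assert res.method == "approximate"
        ref = sps.wilcoxon(d, correction=True, method="approx",
                           zero_method="wilcox").pvalue
        assert res.p_two_sided == pytest.approx(ref, rel=1e-10)


class TestFoldChanges:
    def test_ratio_and_log(self):
        prof = _profiles([("PC(00)", "PC", "WT", 2.0, 3),
                          ("PC(00)", "PC", "KO", 6.0, 3)])
        fc = compute_fold_changes(prof, KO_VS_WT)
        assert fc["fold_change"].iloc[0] == pytest.approx(3.0)
        assert fc["log_fold_change"].iloc[0] == pytest.approx(math.log2(3.0))

    def test_equal_means_give_unit_fc(self):
        prof = _profiles([("PC(00)", "PC", "WT", 5.0, 3),
                          ("PC(00)", "PC", "KO", 5.0, 3)])
        fc = compute_fold_changes(prof, KO_VS_WT)
        assert fc["fold_change"].iloc[0] == 1.0
        assert fc["log_fold_change"].iloc[0] == 0.0

    def test_species_missing_one_genotype_excluded_with_warning(self):
        prof = _profiles([("PC(00)", "PC", "WT", 2.0, 3),
                          ("PC(00)", "PC", "KO", 6.0, 3),
                          ("PC(01)", "PC", "WT", 1.0, 3)])
        with pytest.warns(UserWarning, match="excluded"):
            fc = compute_fold_changes(prof, KO_VS_WT)
        assert list(fc["species_id"]) == ["PC(00)"]

    def test_zero_denominator_excluded_not_raised(self):
        prof = _profiles([("PC(00)", "PC", "WT", 0.0, 3),
                          ("PC(00)", "PC", "KO", 6.0, 3)])
        with pytest.warns(UserWarning):
            fc = compute_fold_changes(prof, KO_VS_WT)
        assert fc.empty


class TestSummarizeClass:
    def _set(self, fcs):
        prof_rows, fc_rows = [], []
        for i, f in enumerate(fcs):
            prof_rows += [(f"PC({i:02d})", "PC", "WT", 1.0, 3),
                          (f"PC({i:02d})", "PC", "KO", f, 3)]
            fc_rows.append((f"PC({i:02d})", "PC", f, math.log2(f)))
        return (pd.DataFrame(fc_rows, columns=["species_id", "class",
                                               "fold_change", "log_fold_change"]),
                _profiles(prof_rows))

    def test_median_of_odd_count(self):
        fc, prof = self._set([2.0, 3.0, 4.0])
        median, total = summarize_class(fc, prof, KO_VS_WT)
        assert median == 3.0
        assert total == pytest.approx(9.0 / 3.0)

    def test_single_species_collapses(self):
        fc, prof = self._set([2.5])
        median, total = summarize_class(fc, prof, KO_VS_WT)
        assert median == total == pytest.approx(2.5)

    def test_unit_fcs_with_unequal_masses(self):
        prof = _profiles([("PC(00)", "PC", "WT", 10.0, 3), ("PC(00)", "PC", "KO", 10.0, 3),
                          ("PC(01)", "PC", "WT", 1.0, 3), ("PC(01)", "PC", "KO", 1.0, 3)])
        fc = compute_fold_changes(prof, KO_VS_WT)
        median, total = summarize_class(fc, prof, KO_VS_WT)
        assert median == 1.0 and total == 1.0


class TestFamilyControl:
    def _results(self, pvals):
        return pd.DataFrame({"class": [f"C{i}" for i in range(len(pvals))],
                             "comparison": "KO_vs_WT", "p_value": pvals})

    @pytest.mark.parametrize("p, marker", [
        (0.0027, "*"),      # pre only at m=26
        (0.0007, "***"),    # survives 0.05/26
        (0.2, ""),
    ])
    def test_markers_at_m26(self, p, marker):
        out = apply_family_control(self._results([p]), FamilyConfig(m=26))
        assert out["marker"].iloc[0] == marker

    def test_post_implies_pre(self):
        out = apply_family_control(self._results([0.0001, 0.01, 0.9]),
                                   FamilyConfig(m=26))
        assert (out.loc[out["significant_post"], "significant_pre"]).all()

    def test_family_undersized_warns(self):
        with pytest.warns(UserWarning, match="family size"):
            apply_family_control(self._results([0.01, 0.02]), FamilyConfig(m=1))

    def test_untestable_rows_never_significant(self):
        out = apply_family_control(self._results([float("nan")]), FamilyConfig(m=26))
        assert not out["significant_pre"].iloc[0]
        assert out["marker"].iloc[0] == ""


class TestClassTestsProperties:
    @pytest.fixture(scope="class")
    def profiles(self):
        from cardiolipidomics import LipidSimConfig, generate_peak_table
        cfg = LipidSimConfig(classes=("AcCa", "PC", "PG"), species_per_class=8,
                             qc_fail_rate=0.0, seed=77)
        profiles, _ = clean_peaks(generate_peak_table(cfg))
        return profiles

    def test_group_swap_symmetry(self, profiles):
        fwd = compute_fold_changes(profiles, ComparisonSpec("KO_vs_WT", "KO", "WT"))
        rev = compute_fold_changes(profiles, ComparisonSpec("WT_vs_KO", "WT", "KO"))
        merged = fwd.merge(rev, on=["species_id", "class"])
        assert np.allclose(merged["fold_change_x"], 1.0 / merged["fold_change_y"])
        for klass in ("AcCa", "PC", "PG"):
            pf = exact_signed_rank(
                fwd.loc[fwd["class"] == klass, "log_fold_change"]).p_two_sided
            pr = exact_signed_rank(
                rev.loc[rev["class"] == klass, "log_fold_change"]).p_two_sided
            assert pf == pytest.approx(pr, abs=1e-12)

    def test_scale_and_log_base_invariance(self, profiles):
        """A global rescaling of concentrations (a unit change) and the choice
        of log base leave every p-value unchanged."""
        scaled = profiles.copy()
        scaled["mean_concentration"] *= 37.0
        base_p, scaled_p = [], []
        for prof, acc in ((profiles, base_p), (scaled, scaled_p)):
            for base in (2.0, math.e, 10.0):
                fc = compute_fold_changes(prof, KO_VS_WT, log_base=base)
                acc.append(exact_signed_rank(
                    fc.loc[fc["class"] == "PC", "log_fold_change"]).p_two_sided)
        assert np.allclose(base_p, base_p[0])
        assert np.allclose(scaled_p, base_p[0])

    def test_long_results_shape_and_flags(self, profiles):
        results = class_tests(profiles, family=FamilyConfig(m=6))
        assert len(results) == 3 * 2
        assert set(results["method"]) <= {"exact", "approximate", "untestable"}
        assert results["n_used"].le(results["n_species"]).all()


class TestReport:
    def test_shape_and_na_rows(self):
        rows = []
        for klass in LIPID_CLASSES:
            for comp in ("HET_vs_WT", "KO_vs_WT"):
                rows.append({"class": klass, "comparison": comp, "n_species": 5,
                             "median_fold_change": 1.5, "total_mass_fold_change": 1.4,
                             "n_used": 5, "w_plus": 15.0, "w_minus": 0.0,
                             "p_value": 0.0625, "method": "exact"})
        results = apply_family_control(pd.DataFrame(rows), FamilyConfig(m=26))
        # make one class untestable
        results.loc[results["class"] == "PG", "p_value"] = np.nan
        report = build_report(results, LIPID_CLASSES)
        assert len(report) == 13
        assert report.loc[report["class"] == "PG", "p_KO_vs_WT"].iloc[0] == "NA"
        assert report.loc[report["class"] == "PC", "p_KO_vs_WT"].iloc[0] == "0.0625"

    def test_report_round_trips_through_text(self, tmp_path):
        from cardiolipidomics.io import read_table, write_table
        rows = [{"class": "PC", "comparison": "KO_vs_WT", "n_species": 3,
                 "median_fold_change": 1.23456, "total_mass_fold_change": 1.2,
                 "n_used": 3, "w_plus": 6.0, "w_minus": 0.0,
                 "p_value": 0.25, "method": "exact"}]
        report = build_report(apply_family_control(pd.DataFrame(rows)),
                              classes=["PC"], comparisons=("KO_vs_WT",))
        path = write_table(report, tmp_path / "report.tsv")
        back = read_table(path)
        assert str(back["fc_KO_vs_WT"].iloc[0]) == report["fc_KO_vs_WT"].iloc[0]
        assert f"{back['p_KO_vs_WT'].iloc[0]:.4f}" == report["p_KO_vs_WT"].iloc[0]
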