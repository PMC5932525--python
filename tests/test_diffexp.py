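"""Presence filter, normality screen, dual-criterion selection."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from itraqpipe import (
    compare,
    fold_change,
    l2r_pvalue,
    min_present,
    normality_screen,
    presence_filter,
    ratio_stats,
    select_differential,
    volcano_table,
    welch_t,
)

from conftest import matrix_from


class TestPresenceFilter:
    def test_minimum_count_for_study_groups(self):
        assert min_present(12, 0.7) == 9

    @pytest.mark.parametrize(
        "size,thr", [(12, 0.7), (10, 0.7), (12, 0.75), (7, 0.5), (12, 1.0)]
    )
    def test_min_present_matches_enumeration(self, size, thr):
        # brute force: smallest k with k/size >= thr
        smallest = next(k for k in range(size + 1) if k / size >= thr)
        assert min_present(size, thr) == smallest

    def test_fully_observed_protein_retained(self, design36, small_matrix):
        full = small_matrix.dropna(axis=0)
        filtered, _ = presence_filter(small_matrix, design36, 0.7)
        assert full.index.isin(filtered.index).all()

    def test_protein_below_threshold_in_one_group_dropped(self, design36):
        # counts (12, 12, 8) over groups of 12: 8 < 9 required -> dropped
        m = matrix_from(np.ones((1, 36)), ["P1"], design36.samples)
        ctrl = [s for s in design36.samples if design36.sample_groups[s] == "Ctrl"]
        m.loc["P1", ctrl[:4]] = np.nan
        filtered, counts = presence_filter(m, design36, 0.7)
        assert counts.loc["P1"].to_dict() == {"G1": 12, "G2": 12, "Ctrl": 8}
        assert "P1" not in filtered.index

    def test_exactly_at_threshold_retained(self, design36):
        m = matrix_from(np.ones((1, 36)), ["P1"], design36.samples)
        ctrl = [s for s in design36.samples if design36.sample_groups[s] == "Ctrl"]
        m.loc["P1", ctrl[:3]] = np.nan  # 9 of 12 = exactly 75% >= 70%
        filtered, _ = presence_filter(m, design36, 0.7)
        assert "P1" in filtered.index

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_threshold_monotonicity(self, design36, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(1, 30, size=(40, 36))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        m = matrix_from(vals, [f"P{i}" for i in range(40)], design36.samples)
        kept = [
            set(presence_filter(m, design36, thr)[0].index)
            for thr in (0.3, 0.5, 0.7, 0.9)
        ]
        for lo, hi in zip(kept, kept[1:]):
            assert hi <= lo

    def test_empty_matrix_warns(self, design36):
        m = matrix_from(np.empty((0, 36)), [], design36.samples)
        with pytest.warns(UserWarning):
            filtered, _ = presence_filter(m, design36, 0.7)
        assert filtered.empty


class TestNormalityScreen:
    def test_gaussian_residuals_pass(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=12), rng.normal(size=12)
        assert normality_screen(a, b, alpha=0.05) is True

    def test_bimodal_residuals_fail(self):
        a = np.array([-1.0] * 6 + [1.0] * 6)
        b = np.array([-1.0] * 6 + [1.0] * 6)
        assert normality_screen(a, b, alpha=0.05) is False

    def test_too_few_observations_fail(self):
        assert normality_screen([1.0, 2.0], [1.0, 2.0, 3.0]) is False

    def test_constant_values_fail(self):
        assert normality_screen([1.0] * 5, [1.0] * 5) is False


class TestWelchT:
    def test_identical_groups_p_one(self):
        assert welch_t([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_separated_groups_p_tiny(self):
        a = np.zeros(4) + 1e-6 * np.array([1, -1, 2, -2])
        b = np.ones(4) + 1e-6 * np.array([1, -1, 2, -2])
        assert welch_t(a, b) < 1e-9

    def test_degenerate_equal_constants_missing(self):
        assert math.isnan(welch_t([1.0, 1.0], [1.0, 1.0]))

    def test_matches_permutation_oracle(self):
        """Welch p for 12-vs-12 Gaussian samples agrees with a Monte-Carlo
        permutation test on the same vectors to within 0.02."""
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(0.6, 1.0, 12)
        p_welch = welch_t(a, b)
        pooled = np.concatenate([a, b])
        t_obs = abs(sps.ttest_ind(a, b, equal_var=False).statistic)
        perm_rng = np.random.default_rng(1)
        hits = 0
        n_perm = 20_000
        for _ in range(n_perm):
            perm = pooled[perm_rng.permutation(24)]
            t = abs(sps.ttest_ind(perm[:12], perm[12:], equal_var=False).statistic)
            if t >= t_obs:
                hits += 1
        p_perm = hits / n_perm
        assert 0.001 < p_welch < 0.5  # informative regime for the comparison
        assert abs(p_welch - p_perm) < 0.02


class TestRatioStats:
    def test_identical_group_means_give_unit_ratio(self, design36):
        m = matrix_from(np.ones((12, 36)) * 5.0, [f"P{i}" for i in range(12)],
                        design36.samples)
        rs = ratio_stats(m, design36, "G1-Ctrl")
        np.testing.assert_allclose(rs["ratio"], 1.0)
        np.testing.assert_allclose(rs["l2r"], 0.0)

    def test_doubled_group_mean_gives_ratio_two(self, design36):
        vals = np.ones((12, 36)) * 5.0
        m = matrix_from(vals, [f"P{i}" for i in range(12)], design36.samples)
        g1 = [s for s in design36.samples if design36.sample_groups[s] == "G1"]
        m.loc["P0", g1] = 10.0
        rs = ratio_stats(m, design36, "G1-Ctrl")
        assert rs.loc["P0", "ratio"] == pytest.approx(2.0)
        assert rs.loc["P0", "l2r"] == pytest.approx(1.0)

    def test_matches_bruteforce_recomputation(self, design36):
        """Independent re-implementation: loop over raw cells with plain
        Python arithmetic and compare every ratio/l2r/centered value."""
        rng = np.random.default_rng(33)
        vals = rng.uniform(5, 40, size=(50, 36))
        vals[rng.random(vals.shape) < 0.15] = np.nan
        prots = [f"P{i}" for i in range(50)]
        m = matrix_from(vals, prots, design36.samples)
        rs = ratio_stats(m, design36, "G1-G2")
        groups = design36.sample_groups
        expected_l2r = {}
        for prot in prots:
            means = {}
            for g in ("G1", "G2"):
                obs = [
                    m.loc[prot, s]
                    for s in design36.samples
                    if groups[s] == g and not math.isnan(m.loc[prot, s])
                ]
                means[g] = sum(obs) / len(obs)
            expected_l2r[prot] = math.log2(means["G1"] / means["G2"])
        center = sum(expected_l2r.values()) / len(expected_l2r)
        for prot in prots:
            assert rs.loc[prot, "l2r"] == pytest.approx(expected_l2r[prot], rel=1e-12)
            assert rs.loc[prot, "l2r_centered"] == pytest.approx(
                expected_l2r[prot] - center, rel=1e-9, abs=1e-12
            )

    def test_centered_values_average_zero(self, design36, small_matrix):
        rs = ratio_stats(small_matrix, design36, "G1-Ctrl")
        assert abs(rs["l2r_centered"].mean()) < 1e-9


class TestL2rPvalue:
    def test_zero_magnitude_p_one(self):
        x = pd.Series(np.concatenate([[0.0], np.linspace(-1, 1, 20)]))
        p = l2r_pvalue(x)
        assert p.iloc[0] == pytest.approx(1.0)

    def test_1p96_sd_gives_p_05(self):
        rng = np.random.default_rng(5)
        x = pd.Series(rng.normal(0, 0.4, 500))
        x -= x.mean()
        sd = x.std(ddof=1)
        x.iloc[0] = 1.96 * sd
        # recompute sd shift is negligible at n=500; use returned value
        p = l2r_pvalue(x)
        assert p.iloc[0] == pytest.approx(
            2 * sps.norm.sf(1.96 * sd / x.std(ddof=1)), rel=1e-9
        )
        assert p.iloc[0] == pytest.approx(0.05, abs=0.002)

    def test_monotone_in_magnitude(self):
        x = pd.Series(np.linspace(-2, 2, 41))
        p = l2r_pvalue(x)
        order = x.abs().sort_values().index
        assert (p.loc[order].diff().dropna() <= 1e-12).all()

    def test_zero_spread_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            p = l2r_pvalue(pd.Series(np.zeros(20)))
        assert (p == 1.0).all()

    def test_too_few_proteins_rejected(self):
        with pytest.raises(ValueError):
            l2r_pvalue(pd.Series(np.linspace(-1, 1, 5)))

    def test_null_calibration(self):
        """Fraction with p < 0.05 under a pure Gaussian null is ~5%."""
        rng = np.random.default_rng(12)
        fracs = [
            (l2r_pvalue(pd.Series(rng.normal(0, 0.3, 2000))) < 0.05).mean()
            for _ in range(20)
        ]
        assert abs(np.mean(fracs) - 0.05) < 0.01


class TestFoldChange:
    @pytest.mark.parametrize(
        "l2r,expected",
        [
            (-0.755, -1.688),  # strongest down-regulation, first comparison
            (-0.622, -1.539),
            (-0.580, -1.495),
            (0.255, 1.193),
            (1.113, 2.163),
            (0.0, 1.000),
        ],
    )
    def test_signed_convention_examples(self, l2r, expected):
        assert round(fold_change(l2r), 3) == expected

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(l2r=st.floats(-10, 10))
    def test_roundtrip_magnitude_and_sign(self, l2r):
        fold = fold_change(l2r)
        assert abs(fold) >= 1.0 or abs(fold) == pytest.approx(1.0)
        assert abs(abs(fold) - 2 ** abs(l2r)) < 1e-9 * 2 ** abs(l2r)
        assert (fold >= 0) == (l2r >= 0)


class TestSelectDifferential:
    def _table(self, t_p, l2r_p, normal=True):
        return pd.DataFrame(
            {"t_p": [t_p], "l2r_p": [l2r_p], "normal_flag": [normal]}, index=["P1"]
        )

    def test_requires_both_criteria(self):
        assert not select_differential(self._table(0.01, 0.20)).iloc[0]
        assert not select_differential(self._table(0.20, 0.01)).iloc[0]
        assert select_differential(self._table(0.01, 0.01)).iloc[0]

    def test_non_normal_never_significant(self):
        assert not select_differential(self._table(0.001, 0.001, normal=False)).iloc[0]

    def test_missing_pvalue_never_significant(self):
        assert not select_differential(self._table(float("nan"), 0.01)).iloc[0]


class TestCompare:
    def test_full_table_contract(self, design36, small_matrix):
        filtered, _ = presence_filter(small_matrix, design36, 0.7)
        table = compare(filtered, design36, "G1-Ctrl")
        # fold change recomputed from l2r matches stored value exactly
        recomputed = fold_change(table["l2r"])
        pd.testing.assert_series_equal(
            recomputed, table["fold_change"], check_names=False
        )
        # significant set is a subset of each single-criterion set
        sig = table.index[table["significant"]]
        assert (table.loc[sig, "t_p"] < 0.05).all()
        assert (table.loc[sig, "l2r_p"] < 0.05).all()
        assert table.loc[sig, "normal_flag"].all()
        # non-normal proteins carry no t-test verdict
        assert table.loc[~table["normal_flag"], "t_p"].isna().all()

    def test_unknown_group_rejected(self, design36, small_matrix):
        with pytest.raises(ValueError):
            compare(small_matrix, design36, "G1-Nope")

    def test_volcano_table_drops_untested(self, design36, small_matrix):
        filtered, _ = presence_filter(small_matrix, design36, 0.7)
        table = compare(filtered, design36, "G2-Ctrl")
        v = volcano_table(table)
        assert set(v.columns) == {"l2r_centered", "minus_log10_t_p"}
        assert len(v) == int(table["t_p"].notna().sum())
        assert np.isfinite(v["minus_log10_t_p"]).all()

    def test_bh_flag_only_shrinks_discoveries(self, design36, small_matrix):
        filtered, _ = presence_filter(small_matrix, design36, 0.7)
        plain = compare(filtered, design36, "G1-Ctrl")
        adjusted = compare(filtered, design36, "G1-Ctrl", bh_correction=True)
        sig_adj = set(adjusted.index[adjusted["significant"]])
        sig_plain = set(plain.index[plain["significant"]])
        assert sig_adj <= sig_plain
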