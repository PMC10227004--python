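"""Restitution curves/slopes, nonparametric statistics, Teichholz EF."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import voltmap as vm
from voltmap.restitution_stats import (build_restitution, dunn_posthoc,
                                       kruskal_wallis, restitution_slope,
                                       summarize_groups, teichholz_ef,
                                       teichholz_volume, trend_test)


class TestBuildRestitution:
    def test_pairs_sorted_by_di(self):
        curve = build_restitution({400.0: 100.0, 300.0: 90.0, 250.0: 85.0,
                                   200.0: 70.0})
        assert curve.points == [(130.0, 70.0), (165.0, 85.0),
                                (210.0, 90.0), (300.0, 100.0)]

    def test_failing_heart_means_give_expected_dis(self):
        curve = build_restitution({400.0: 108.362, 300.0: 93.684,
                                   250.0: 84.198, 200.0: 67.809})
        assert curve.di.tolist() == pytest.approx(
            [132.191, 165.802, 206.316, 291.638])

    def test_single_cl_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            build_restitution({400.0: 100.0})

    def test_apd_longer_than_cl_rejected(self):
        with pytest.raises(ValueError):
            build_restitution({400.0: 100.0, 200.0: 210.0})


class TestRestitutionSlope:
    def test_collinear_points_exact(self):
        di = np.array([100.0, 150.0, 220.0, 300.0])
        curve = build_restitution({d + 50 + 0.1 * d: 50 + 0.1 * d
                                   for d in di})
        assert restitution_slope(curve, "segmentwise") == pytest.approx(
            0.1, abs=1e-12)
        assert restitution_slope(curve, "exponential") == pytest.approx(
            0.1, rel=0.05)

    def test_flat_segment_gives_zero(self):
        curve = vm.RestitutionCurve(points=[(100.0, 80.0), (200.0, 80.0)])
        assert restitution_slope(curve) == 0.0

    def test_exponential_fit_recovers_parameters(self):
        a, b, tau = 110.0, 70.0, 80.0
        di = np.linspace(40, 320, 8)
        apd = a - b * np.exp(-di / tau)
        curve = vm.RestitutionCurve(points=list(zip(di, apd)))
        slope = restitution_slope(curve, "exponential")
        expected = b / tau * np.exp(-di.min() / tau)
        assert slope == pytest.approx(expected, rel=0.01)
        assert curve.slope_summary["A"] == pytest.approx(a, rel=0.01)
        assert curve.slope_summary["tau"] == pytest.approx(tau, rel=0.01)

    def test_non_monotone_di_rejected(self):
        curve = vm.RestitutionCurve(points=[(200.0, 80.0), (100.0, 70.0)])
        with pytest.raises(ValueError):
            restitution_slope(curve)

    def test_hf_steeper_than_control_in_cohort(self, cohort):
        df = cohort["df"]
        slopes = {}
        for grp in ("control", "hf"):
            sub = df[(df["group"] == grp) & df["apd80_ms"].notna()]
            by_cl = sub.groupby("cl_ms")["apd80_ms"].mean().to_dict()
            slopes[grp] = restitution_slope(build_restitution(by_cl))
        assert slopes["hf"] > slopes["control"]


class TestKruskalWallis:
    def test_hand_computed_h(self):
        # ranks 1..6, no ties: H = 12/42 * (36/3 + 225/3) - 21 = 27/7
        h, p = kruskal_wallis([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert h == pytest.approx(27.0 / 7.0, abs=1e-9)

    def test_identical_groups_degenerate(self):
        h, p = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert h == 0.0 and p == 1.0

    def test_matches_exhaustive_permutation_oracle_small_n(self):
        """For total n <= 8 the reported p equals the exact permutation
        p (oracle: enumerate group assignments, score with scipy H)."""
        rng = np.random.default_rng(3)
        for _ in range(4):
            pooled = rng.permutation(np.arange(1.0, 9.0))
            groups = [pooled[:3], pooled[3:6], pooled[6:]]
            h_obs = sps.kruskal(*groups)[0]
            hits = total = 0
            for combo in itertools.combinations(range(8), 3):
                rest = [i for i in range(8) if i not in combo]
                for combo2 in itertools.combinations(rest, 3):
                    g3 = [i for i in rest if i not in combo2]
                    h = sps.kruskal(pooled[list(combo)],
                                    pooled[list(combo2)],
                                    pooled[g3])[0]
                    total += 1
                    hits += h >= h_obs - 1e-9
            _, p = kruskal_wallis(groups)
            assert p == pytest.approx(hits / total, abs=1e-2)

    def test_chi2_method_matches_scipy(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=6) for _ in range(3)]
        h, p = kruskal_wallis(groups, method="chi2")
        assert p == pytest.approx(sps.kruskal(*groups)[1])

    def test_permutation_close_to_chi2_but_calibrated(self):
        """The sampled permutation null (default at cohort sizes) must
        land near the chi-square value and be seed-stable."""
        rng = np.random.default_rng(1)
        groups = [rng.normal(size=n) for n in (5, 5, 4, 4)]
        _, p1 = kruskal_wallis(groups)
        _, p2 = kruskal_wallis(groups)
        assert p1 == p2
        _, p_chi2 = kruskal_wallis(groups, method="chi2")
        assert abs(p1 - p_chi2) < 0.08

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestDunn:
    def test_identical_groups_all_p_one(self):
        unadj, adj = dunn_posthoc([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]],
                                  force=True)
        assert (unadj.values == 1.0).all()
        assert (adj.values == 1.0).all()

    def test_symmetry_and_holm_ordering(self, rng):
        groups = [rng.normal(size=7), rng.normal(1.0, size=6),
                  rng.normal(2.0, size=5)]
        unadj, adj = dunn_posthoc(groups)
        assert np.allclose(unadj.values, unadj.values.T)
        assert np.allclose(adj.values, adj.values.T)
        assert (unadj.values <= adj.values + 1e-12).all()

    def test_two_group_z_squared_equals_h(self):
        """With two tie-free groups Dunn's z satisfies z^2 = H, so
        p_dunn = 2 Phi(-sqrt(H)) — an independent closed-form check."""
        rng = np.random.default_rng(5)
        g1, g2 = rng.normal(size=6), rng.normal(0.8, size=5)
        h, _ = kruskal_wallis([g1, g2], method="chi2")
        unadj, _ = dunn_posthoc([g1, g2], force=True)
        expected = 2.0 * sps.norm.sf(np.sqrt(h))
        assert unadj.iloc[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_shifted_group_has_smallest_p(self, rng):
        base = rng.normal(size=(3, 20))
        base[2] += 3.0
        unadj, _ = dunn_posthoc(list(base), force=True)
        assert unadj.iloc[0, 2] < unadj.iloc[0, 1]
        assert unadj.iloc[1, 2] < unadj.iloc[0, 1]

    def test_gating_on_omnibus(self):
        groups = [[1.0, 2.0], [1.5, 2.5]]
        with pytest.raises(ValueError, match="gated"):
            dunn_posthoc(groups, omnibus_p=0.8)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dunn_posthoc([[1.0], []], force=True)


class TestTrend:
    def test_perfect_linear_trend(self):
        sign, p, slope = trend_test({400.0: [10.0], 300.0: [20.0],
                                     250.0: [30.0], 200.0: [40.0]})
        assert sign == 1 and p < 1e-6
        assert slope == pytest.approx(10.0)

    def test_decreasing_apd_gives_negative_trend(self, cohort):
        df = cohort["df"]
        sub = df[(df["group"] == "control") & df["apd80_ms"].notna()]
        by_level = {cl: g["apd80_ms"].tolist()
                    for cl, g in sub.groupby("cl_ms")}
        sign, p, _ = trend_test(by_level)
        assert sign == -1
        assert p < 0.05

    def test_empty_level_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            sign, p, _ = trend_test({400.0: [1.0, 2.0], 300.0: [],
                                     250.0: [2.0, 3.0], 200.0: [3.0, 4.0]})
        assert np.isfinite(p)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            trend_test({400.0: [1.0], 300.0: [2.0]})


class TestTeichholz:
    def test_equal_diameters_zero_ef(self):
        assert teichholz_ef(1.2, 1.2) == 0.0

    def test_worked_example(self):
        # V(1.5) = 7/3.9 * 3.375 = 6.0577 mL; V(1.0) = 7/3.4 = 2.0588 mL
        assert teichholz_volume(1.5) == pytest.approx(6.0577, abs=1e-3)
        assert teichholz_volume(1.0) == pytest.approx(2.0588, abs=1e-3)
        assert teichholz_ef(1.5, 1.0) == pytest.approx(66.01, abs=0.05)

    def test_small_systolic_limit(self):
        assert teichholz_ef(1.5, 1e-6) == pytest.approx(100.0, abs=1e-3)

    @settings(deadline=None, derandomize=True)
    @given(lvedd=st.floats(0.5, 3.0),
           frac=st.floats(0.05, 0.95),
           dfrac=st.floats(0.01, 0.2))
    def test_ef_strictly_decreases_in_lvesd(self, lvedd, frac, dfrac):
        lvesd = lvedd * frac
        lvesd2 = min(lvesd * (1 + dfrac), lvedd)
        if lvesd2 > lvesd:
            assert teichholz_ef(lvedd, lvesd2) < teichholz_ef(lvedd, lvesd)

    def test_invalid_diameters_rejected(self):
        with pytest.raises(ValueError):
            teichholz_ef(1.0, 1.5)
        with pytest.raises(ValueError):
            vm.EchoMeasures(lvedd=1.0, lvesd=1.5)


class TestSummarizeGroups:
    @staticmethod
    def _df(groups, cls=(400.0, 300.0, 250.0)):
        rows = []
        rng = np.random.default_rng(0)
        for g, n in groups.items():
            for i in range(n):
                for j, cl in enumerate(cls):
                    rows.append({"subject_id": f"{g}{i}", "group": g,
                                 "cl_ms": cl,
                                 "apd80_ms": 100.0 - 10 * j
                                 + rng.normal(0, 2)
                                 + (20.0 if g == "hf" else 0.0)})
        return pd.DataFrame(rows)

    def test_mean_sd_hand_values(self):
        df = pd.DataFrame({
            "subject_id": ["a", "b", "c"], "group": ["g"] * 3,
            "cl_ms": [400.0] * 3, "apd80_ms": [100.0, 105.0, 110.0]})
        df = pd.concat([df, df.assign(cl_ms=300.0),
                        df.assign(cl_ms=250.0)])
        table = summarize_groups(df, "apd80_ms")
        row = table.summary.iloc[0]
        assert row["g_mean"] == pytest.approx(105.0)
        assert row["g_sd"] == pytest.approx(5.0)
        assert row["g_n"] == 3

    def test_single_subject_sd_missing(self):
        df = pd.DataFrame({"subject_id": ["a"], "group": ["g"],
                           "cl_ms": [400.0], "apd80_ms": [100.0]})
        table = summarize_groups(df, "apd80_ms")
        assert np.isnan(table.summary.iloc[0]["g_sd"])

    def test_study_design_group_sizes(self):
        df = self._df({"sham": 5, "rdn": 5, "hf": 4, "rdnhf": 4})
        table = summarize_groups(df, "apd80_ms",
                                 group_order=["sham", "rdn", "hf", "rdnhf"])
        row = table.summary.iloc[0]
        assert (row["sham_n"], row["rdn_n"], row["hf_n"],
                row["rdnhf_n"]) == (5, 5, 4, 4)
        assert 0.0 <= row["p_value"] <= 1.0
        assert set(table.trend) == {"sham", "rdn", "hf", "rdnhf"}

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            summarize_groups(pd.DataFrame({"x": [1]}), "apd80_ms")
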