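import numpy as np
import pytest
from scipy import stats as sps

from adiponet.cohort_stats import (
    assess_normality,
    compare_groups,
    compare_paired,
    compare_two_groups,
    dunn_posthoc,
    normality_zscores,
    two_way_anova,
)


class TestAssessNormality:
    def test_normal_sample_routes_parametric(self, rng):
        assert assess_normality(rng.normal(size=200)) == "parametric"

    def test_exponential_sample_routes_nonparametric(self, rng):
        assert assess_normality(rng.exponential(size=200)) == "nonparametric"

    def test_constant_vector_warns_and_routes_nonparametric(self):
        with pytest.warns(UserWarning, match="constant"):
            assert assess_normality(np.ones(50)) == "nonparametric"

    def test_tiny_sample_warns_and_routes_nonparametric(self):
        with pytest.warns(UserWarning, match="too small"):
            assert assess_normality([1.0, 2.0, 3.0]) == "nonparametric"

    def test_omnibus_matches_chi_square_of_z_scores(self, rng):
        """Independent reference: K2 = z_s^2 + z_k^2 against chi2(2)."""
        x = rng.normal(size=150)
        z_s, z_k, p = normality_zscores(x)
        assert p == pytest.approx(sps.chi2.sf(z_s**2 + z_k**2, df=2), rel=1e-10)

    def test_borderline_z_outside_band_routes_nonparametric(self, rng):
        # mildly skewed: omnibus may not reject but the z-band rule must
        x = rng.normal(size=5000) + 0.1 * rng.exponential(size=5000)
        z_s, _, _ = normality_zscores(x)
        if abs(z_s) >= 1.96:
            assert assess_normality(x) == "nonparametric"


def _brute_force_anova(groups):
    """One-way ANOVA from the sums-of-squares definitions."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((g - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, sps.f.sf(f, df_b, df_w)


class TestCompareGroups:
    TOY = [
        np.array([3.1, 2.9, 3.4, 3.0]),
        np.array([3.6, 3.9, 3.5, 4.0]),
        np.array([2.6, 2.2, 2.8, 2.4]),
    ]

    def _stack(self, groups):
        values = np.concatenate(groups)
        labels = np.concatenate(
            [[f"g{i}"] * len(g) for i, g in enumerate(groups)]
        )
        return values, labels

    def test_parametric_branch_matches_brute_force_oracle(self):
        values, labels = self._stack(self.TOY)
        res = compare_groups(values, labels)
        f_expected, p_expected = _brute_force_anova(self.TOY)
        assert res.branch == "parametric"
        assert res.statistic == pytest.approx(f_expected, abs=1e-8)
        assert res.p_value == pytest.approx(p_expected, abs=1e-8)
        assert len(res.posthoc) == 3

    def test_shifted_group_detected_with_posthocs(self, rng):
        groups = [rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(3, 1, 20)]
        values, labels = self._stack(groups)
        res = compare_groups(values, labels)
        assert res.p_value < 1e-3
        sig = {
            frozenset(e["pair"]) for e in res.posthoc if e["p"] < 0.05
        }
        assert frozenset(("g0", "g2")) in sig
        assert frozenset(("g1", "g2")) in sig

    def test_nonparametric_branch_runs_kruskal_and_dunn(self, rng):
        groups = [rng.exponential(size=30) for _ in range(3)]
        values, labels = self._stack(groups)
        res = compare_groups(values, labels)
        assert res.branch == "nonparametric"
        assert res.test_name == "kruskal-wallis"
        h, p = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(h, abs=1e-10)
        assert all("p_unadjusted" in e for e in res.posthoc)

    def test_two_groups_dispatch_to_two_group_path(self, rng):
        values = np.concatenate([rng.normal(size=30), rng.normal(1, 1, 30)])
        labels = ["a"] * 30 + ["b"] * 30
        res = compare_groups(values, labels)
        assert res.test_name in ("t-test", "mann-whitney")
        assert res.posthoc == []

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_two_groups([1.0, 2.0], ["a", "a"])


class TestDunn:
    def test_matches_hand_computed_rank_statistics(self):
        # no ties: ranks 1..6, rank means 1.5 / 3.5 / 5.5,
        # variance term N(N+1)/12 = 3.5, se = sqrt(3.5 * (1/2 + 1/2))
        samples = {
            "a": np.array([1.0, 2.0]),
            "b": np.array([3.0, 4.0]),
            "c": np.array([5.0, 6.0]),
        }
        out = dunn_posthoc(samples)
        se = np.sqrt(3.5)
        z_ab = (1.5 - 3.5) / se
        first = out[0]
        assert first["pair"] == ("a", "b")
        assert first["statistic"] == pytest.approx(z_ab, abs=1e-12)
        assert first["p_unadjusted"] == pytest.approx(
            2 * sps.norm.sf(abs(z_ab)), abs=1e-12
        )
        assert first["p"] == pytest.approx(
            min(1.0, 3 * first["p_unadjusted"]), abs=1e-12
        )

    def test_tie_correction_shrinks_variance(self):
        tied = {
            "a": np.array([1.0, 1.0, 1.0]),
            "b": np.array([1.0, 2.0, 2.0]),
            "c": np.array([3.0, 3.0, 4.0]),
        }
        untied = {
            "a": np.array([1.0, 1.1, 1.2]),
            "b": np.array([1.3, 2.0, 2.1]),
            "c": np.array([3.0, 3.1, 4.0]),
        }
        z_tied = abs(dunn_posthoc(tied)[0]["statistic"])
        z_untied = abs(dunn_posthoc(untied)[0]["statistic"])
        assert z_tied > 0 and z_untied > 0  # smoke: tie path exercised


class TestComparePaired:
    def test_identical_series_gives_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="zero"):
            res = compare_paired(x, x)
        assert res.p_value == 1.0

    def test_t_statistic_matches_closed_form(self, rng):
        pre = rng.normal(size=10)
        post = pre + rng.normal(0.2, 0.3, size=10)
        res = compare_paired(pre, post)
        d = post - pre
        if res.branch == "parametric":
            t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            assert res.statistic == pytest.approx(t_oracle, abs=1e-8)

    def test_strong_shift_detected(self, rng):
        pre = rng.normal(size=30)
        res = compare_paired(pre, pre + 1)
        assert res.p_value < 1e-6

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_paired([1.0, 2.0, 3.0], [1.0, 2.0])


def _brute_force_two_way(values, a, b):
    """Balanced two-way ANOVA from cell-mean sums of squares."""
    values = np.asarray(values, float)
    a = np.asarray(a)
    b = np.asarray(b)
    la, lb = np.unique(a), np.unique(b)
    r = len(values) // (len(la) * len(lb))
    grand = values.mean()
    mean_a = {x: values[a == x].mean() for x in la}
    mean_b = {x: values[b == x].mean() for x in lb}
    cell = {(x, y): values[(a == x) & (b == y)].mean() for x in la for y in lb}
    ss_a = len(lb) * r * sum((mean_a[x] - grand) ** 2 for x in la)
    ss_b = len(la) * r * sum((mean_b[y] - grand) ** 2 for y in lb)
    ss_ab = r * sum(
        (cell[(x, y)] - mean_a[x] - mean_b[y] + grand) ** 2
        for x in la
        for y in lb
    )
    ss_e = sum(
        ((values[(a == x) & (b == y)] - cell[(x, y)]) ** 2).sum()
        for x in la
        for y in lb
    )
    df_e = len(values) - len(la) * len(lb)
    mse = ss_e / df_e
    return (
        (ss_a / (len(la) - 1)) / mse,
        (ss_b / (len(lb) - 1)) / mse,
        (ss_ab / ((len(la) - 1) * (len(lb) - 1))) / mse,
    )


class TestTwoWayAnova:
    def test_balanced_design_matches_brute_force_oracle(self, rng):
        a = np.repeat(["ctl", "lps"], 8)
        b = np.tile(np.repeat(["veh", "rosi"], 4), 2)
        values = rng.normal(size=16) + (a == "lps") * 0.5 + (b == "rosi") * 1.0
        res = two_way_anova(values, a, b)
        f_a, f_b, f_ab = _brute_force_two_way(values, a, b)
        assert res.effects["factor_a"]["F"] == pytest.approx(f_a, abs=1e-8)
        assert res.effects["factor_b"]["F"] == pytest.approx(f_b, abs=1e-8)
        assert res.effects["interaction"]["F"] == pytest.approx(f_ab, abs=1e-8)
        assert res.branch == "parametric"
        assert len(res.posthoc) == 6  # 4 cells -> 6 pairs

    def test_constant_factor_rejected(self, rng):
        with pytest.raises(ValueError, match="two levels"):
            two_way_anova(rng.normal(size=8), ["x"] * 8, ["u", "v"] * 4)

    def test_empty_cell_rejected(self, rng):
        a = ["x"] * 4 + ["y"] * 4
        b = ["u", "u", "v", "v", "u", "u", "u", "u"]  # (y, v) missing
        with pytest.raises(ValueError, match="empty design cell"):
            two_way_anova(rng.normal(size=8), a, b)
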