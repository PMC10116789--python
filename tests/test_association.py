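import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from adiponet.association import (
    correlation_matrix,
    correlation_matrix_to_frame,
    delta_correlation,
    pearson_with_log_routing,
    significance_stars,
)


def _brute_force_pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())


class TestPearsonRouting:
    def test_identity_gives_r_one(self, rng):
        x = rng.normal(size=50)
        res = pearson_with_log_routing(x, x.copy(), log_routing=False)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p_value < 1e-30

    def test_negation_gives_r_minus_one(self, rng):
        x = rng.normal(size=50)
        res = pearson_with_log_routing(x, -x, log_routing=False)
        assert res.r == pytest.approx(-1.0, abs=1e-12)

    def test_toy_vectors_match_covariance_definition(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.5]
        y = [2.1, 1.9, 3.5, 3.2, 5.0, 6.1]
        res = pearson_with_log_routing(x, y, log_routing=False)
        assert res.r == pytest.approx(_brute_force_pearson(x, y), abs=1e-12)

    def test_p_value_matches_t_transform(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        res = pearson_with_log_routing(x, y, log_routing=False)
        from scipy import stats as sps

        t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        assert res.p_value == pytest.approx(
            2 * sps.t.sf(abs(t), res.n - 2), rel=1e-10
        )

    def test_p_value_agrees_with_permutation_null(self, rng):
        x = rng.normal(size=12)
        y = x + rng.normal(0, 2, size=12)
        res = pearson_with_log_routing(x, y, log_routing=False)
        r_obs = abs(_brute_force_pearson(x, y))
        perm_rng = np.random.default_rng(0)
        exceed = sum(
            abs(_brute_force_pearson(x, perm_rng.permutation(y))) >= r_obs
            for _ in range(10_000)
        )
        p_perm = exceed / 10_000
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / 10_000 + 1e-6)
        assert abs(res.p_value - p_perm) <= max(0.02, mc_err + 0.01)

    def test_non_normal_variable_gets_logged(self, rng):
        from scipy import stats as sps

        x = rng.lognormal(size=200)
        # exactly normal-shaped sample: passes the z-band screen by design
        y = rng.permutation(sps.norm.ppf((np.arange(200) + 0.5) / 200))
        res = pearson_with_log_routing(x, y, name_x="lps")
        assert res.log_x
        assert not res.log_y

    def test_log_routing_preserves_monotone_sign(self, rng):
        x = rng.lognormal(size=200)
        y = 2 * x + rng.lognormal(size=200) * 0.1
        raw = pearson_with_log_routing(x, y, log_routing=False)
        routed = pearson_with_log_routing(x, y)
        assert np.sign(raw.r) == np.sign(routed.r) == 1.0

    def test_nonpositive_value_in_logged_variable_rejected(self, rng):
        x = np.concatenate([rng.lognormal(size=199), [-1.0]])
        with pytest.raises(ValueError, match="lps"):
            pearson_with_log_routing(x, rng.normal(size=200), name_x="lps")

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_with_log_routing([1.0] * 10, list(range(10)))

    @given(
        a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-5, 5),
    )
    def test_affine_transform_gives_sign_of_slope(self, a, b):
        x = np.linspace(1.0, 9.0, 12)
        res = pearson_with_log_routing(x, a * x + b, log_routing=False)
        assert res.r == pytest.approx(np.sign(a), abs=1e-9)


def _paired_frame(dx, dy, rng):
    n = len(dx)
    pre_x = rng.lognormal(size=n) + 5
    pre_y = rng.lognormal(size=n) + 5
    rows = []
    for i in range(n):
        rows.append((f"p{i}", "pre", pre_x[i], pre_y[i]))
        rows.append((f"p{i}", "post", pre_x[i] + dx[i], pre_y[i] + dy[i]))
    return pd.DataFrame(
        rows, columns=["subject_id", "timepoint", "endotoxin", "CIDEA"]
    )


class TestDeltaCorrelation:
    def test_recovers_planted_delta_coupling(self, rng):
        cov = np.array([[1.0, -0.5], [-0.5, 1.0]])
        d = rng.multivariate_normal([0, 0], cov, size=1000)
        frame = _paired_frame(d[:, 0], d[:, 1], rng)
        res = delta_correlation(frame, "endotoxin", "CIDEA")
        assert -0.56 <= res.r <= -0.44
        assert res.n == 1000

    def test_sign_flip_negates_r_exactly(self, rng):
        d = rng.normal(size=(30, 2))
        f1 = _paired_frame(d[:, 0], d[:, 1], np.random.default_rng(1))
        f2 = _paired_frame(d[:, 0], -d[:, 1], np.random.default_rng(1))
        r1 = delta_correlation(f1, "endotoxin", "CIDEA").r
        r2 = delta_correlation(f2, "endotoxin", "CIDEA").r
        assert r2 == pytest.approx(-r1, abs=1e-12)

    def test_zero_variance_deltas_rejected(self, rng):
        frame = _paired_frame(np.zeros(10), rng.normal(size=10), rng)
        with pytest.raises(ValueError, match="variance"):
            delta_correlation(frame, "endotoxin", "CIDEA")

    def test_incomplete_subjects_excluded(self, rng):
        frame = _paired_frame(rng.normal(size=10), rng.normal(size=10), rng)
        frame = frame.drop(frame[(frame.subject_id == "p0") & (frame.timepoint == "post")].index)
        res = delta_correlation(frame, "endotoxin", "CIDEA")
        assert res.n == 9

    def test_fewer_than_three_complete_rejected(self, rng):
        frame = _paired_frame(rng.normal(size=2), rng.normal(size=2), rng)
        with pytest.raises(ValueError, match="at least 3"):
            delta_correlation(frame, "endotoxin", "CIDEA")


class TestCorrelationMatrix:
    def test_self_cell_is_unity(self, rng):
        frame = pd.DataFrame({"g": rng.normal(size=30)})
        out = correlation_matrix(frame, ["g"], ["g"])
        assert out[("g", "g")].r == 1.0

    def test_unknown_gene_listed_in_error(self, rng):
        frame = pd.DataFrame({"g": rng.normal(size=30)})
        with pytest.raises(ValueError, match="nope"):
            correlation_matrix(frame, ["g"], ["nope"])

    def test_independent_panels_stay_near_zero(self):
        from adiponet import synthetic as syn

        variables = syn.SyntheticConfig().variables
        identity = pd.DataFrame(
            np.eye(len(variables)), index=variables, columns=variables
        )
        cfg = syn.SyntheticConfig(
            n_lean=0, n_overweight=2000, n_obese=0,
            target_correlation=identity, group_shifts={"overweight": {}}, seed=4,
        )
        expr, _, _ = syn.generate_cohort(cfg)
        out = correlation_matrix(expr, cfg.bat_genes, cfg.inflammatory_genes)
        assert max(abs(res.r) for res in out.values()) <= 0.07

    def test_planted_cross_block_correlation_recovered(self):
        from adiponet import synthetic as syn

        cfg0 = syn.SyntheticConfig()
        target = cfg0.target_correlation.copy()
        for bg in cfg0.bat_genes:
            for ig in cfg0.inflammatory_genes:
                target.loc[bg, ig] = target.loc[ig, bg] = -0.3
        cfg = syn.SyntheticConfig(
            n_lean=0, n_overweight=5000, n_obese=0,
            target_correlation=target, group_shifts={"overweight": {}}, seed=8,
        )
        expr, _, _ = syn.generate_cohort(cfg)
        logged = expr.copy()
        logged[cfg.genes] = np.log(expr[cfg.genes])
        out = correlation_matrix(
            logged, cfg.bat_genes, cfg.inflammatory_genes, log_routing=False
        )
        for res in out.values():
            assert res.r == pytest.approx(-0.3, abs=0.05)

    def test_flat_export_carries_stars(self, rng):
        frame = pd.DataFrame(
            {"a": rng.normal(size=40), "b": rng.normal(size=40)}
        )
        frame["c"] = frame["a"] + 0.1 * rng.normal(size=40)
        out = correlation_matrix_to_frame(
            correlation_matrix(frame, ["a"], ["c"], log_routing=False)
        )
        assert set(out.columns) >= {"r", "p_value", "n", "stars"}
        assert out["stars"].iloc[0] == "****"


@pytest.mark.parametrize(
    "p,expected",
    [(0.2, "ns"), (0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.00009, "****")],
)
def test_star_convention(p, expected):
    assert significance_stars(p) == expected
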