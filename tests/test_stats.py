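"""Mixed repeated-measures ANOVA against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps

from lingua_rt import (
    estimated_marginal_means,
    gg_epsilon,
    mauchly_test,
    mixed_anova,
    observed_power,
    pooled_within_covariance,
    rm_anova_single,
)
from lingua_rt.stats import _wide_by_group

from conftest import rm_table


def brute_force_split_plot(values_by_group):
    """Independent sums-of-squares oracle from cell-mean definitions."""
    groups = list(values_by_group)
    mats = [np.asarray(values_by_group[g], float) for g in groups]
    k = mats[0].shape[1]
    ns = [m.shape[0] for m in mats]
    n = sum(ns)
    allv = np.vstack(mats)
    grand = allv.mean()
    ss = {}
    ss["total"] = sum((x - grand) ** 2 for x in allv.ravel())
    ss["between_subj"] = sum(
        k * (row.mean() - grand) ** 2 for m in mats for row in m
    )
    ss["group"] = sum(k * m.shape[0] * (m.mean() - grand) ** 2 for m in mats)
    ss["subj_within"] = ss["between_subj"] - ss["group"]
    ss["harmonic"] = sum(n * (allv[:, h].mean() - grand) ** 2 for h in range(k))
    ss["cells"] = sum(
        m.shape[0] * (m[:, h].mean() - grand) ** 2 for m in mats for h in range(k)
    )
    ss["interaction"] = ss["cells"] - ss["harmonic"] - ss["group"]
    ss["error"] = (
        ss["total"] - ss["between_subj"] - ss["harmonic"] - ss["interaction"]
    )
    g = len(mats)
    df = dict(group=g - 1, subj=n - g, harm=k - 1, inter=(g - 1) * (k - 1),
              err=(n - g) * (k - 1))
    f_group = (ss["group"] / df["group"]) / (ss["subj_within"] / df["subj"])
    f_harm = (ss["harmonic"] / df["harm"]) / (ss["error"] / df["err"])
    f_inter = (ss["interaction"] / df["inter"]) / (ss["error"] / df["err"])
    return ss, (f_group, f_harm, f_inter)


class TestMixedAnovaOracles:
    @pytest.mark.parametrize("ns,k,seed", [((3, 2), 3, 0), ((6, 5), 11, 1), ((4, 4), 5, 2)])
    def test_matches_brute_force_decomposition(self, ns, k, seed):
        rng = np.random.default_rng(seed)
        vals = {
            "a": rng.normal(30, 4, (ns[0], k)) + np.linspace(0, -6, k),
            "b": rng.normal(22, 4, (ns[1], k)),
        }
        res = mixed_anova(rm_table(vals))
        ss, (fg, fh, fi) = brute_force_split_plot(vals)
        assert res.ss_group == pytest.approx(ss["group"], abs=1e-8)
        assert res.ss_harmonic == pytest.approx(ss["harmonic"], abs=1e-8)
        assert res.ss_interaction == pytest.approx(ss["interaction"], abs=1e-8)
        assert res.ss_error_within == pytest.approx(ss["error"], abs=1e-8)
        assert res.ss_subjects_within_group == pytest.approx(ss["subj_within"], abs=1e-8)
        assert res.F_group == pytest.approx(fg, abs=1e-8)
        assert res.F_harmonic == pytest.approx(fh, abs=1e-8)
        assert res.F_interaction == pytest.approx(fi, abs=1e-8)

    @pytest.mark.parametrize("ns,k,seed", [((6, 5), 11, 3), ((4, 6), 4, 4)])
    def test_matches_pingouin(self, ns, k, seed):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(seed)
        vals = {
            "a": rng.normal(30, 4, (ns[0], k)),
            "b": rng.normal(22, 4, (ns[1], k)) + np.linspace(0, 5, k),
        }
        table = rm_table(vals)
        res = mixed_anova(table)
        aov = pg.mixed_anova(
            data=table, dv="value_px", within="harmonic",
            subject="subject_id", between="group",
        )
        assert res.ss_group == pytest.approx(aov.loc[0, "SS"], abs=1e-8)
        assert res.ss_harmonic == pytest.approx(aov.loc[1, "SS"], abs=1e-8)
        assert res.ss_interaction == pytest.approx(aov.loc[2, "SS"], abs=1e-8)
        assert res.F_interaction == pytest.approx(aov.loc[2, "F"], abs=1e-8)
        assert res.p_interaction_uncorrected == pytest.approx(
            aov.loc[2, "p_unc"], abs=1e-10
        )

    def test_ss_decomposition_exact(self):
        rng = np.random.default_rng(5)
        vals = {"a": rng.normal(size=(5, 7)), "b": rng.normal(size=(3, 7))}
        res = mixed_anova(rm_table(vals))
        total = (
            res.ss_group
            + res.ss_subjects_within_group
            + res.ss_harmonic
            + res.ss_interaction
            + res.ss_error_within
        )
        assert total == pytest.approx(res.ss_total, rel=1e-12)

    def test_two_level_single_group_equals_paired_t(self):
        rng = np.random.default_rng(6)
        x = rng.normal(10, 2, (8, 2))
        f, df1, df2, p = rm_anova_single(x)
        t, pt = sps.ttest_rel(x[:, 0], x[:, 1])
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)

    def test_identical_groups_null_result(self):
        rng = np.random.default_rng(7)
        base = rng.normal(25, 3, (4, 6))
        res = mixed_anova(rm_table({"a": base, "b": base.copy()}))
        assert res.F_group == pytest.approx(0.0, abs=1e-12)
        assert res.p_group == pytest.approx(1.0)
        assert res.F_interaction == pytest.approx(0.0, abs=1e-10)

    def test_missing_cells_rejected(self):
        t = rm_table({"a": np.zeros((3, 4)), "b": np.ones((3, 4))})
        t = t.drop(index=2)
        with pytest.raises(ValueError, match="missing cells"):
            mixed_anova(t)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            mixed_anova(rm_table({"a": np.random.default_rng(0).normal(size=(4, 3))}))

    def test_tiny_group_rejected(self):
        vals = {"a": np.random.default_rng(0).normal(size=(4, 3)),
                "b": np.random.default_rng(1).normal(size=(1, 3))}
        with pytest.raises(ValueError, match="2 subjects"):
            mixed_anova(rm_table(vals))

    def test_zero_error_variance_reports_inf_with_warning(self):
        a = np.tile([10.0, 20.0, 30.0], (3, 1))
        b = np.tile([12.0, 25.0, 28.0], (3, 1))
        with pytest.warns(UserWarning, match="zero error variance"):
            res = mixed_anova(rm_table({"a": a, "b": b}))
        assert np.isinf(res.F_harmonic)


class TestGreenhouseGeisser:
    def test_compound_symmetry_gives_one(self):
        s = 0.5 * np.ones((11, 11)) + 0.8 * np.eye(11)
        assert gg_epsilon(s) == pytest.approx(1.0)

    def test_rank_one_hits_lower_bound(self):
        v = np.random.default_rng(0).normal(size=11)
        assert gg_epsilon(np.outer(v, v)) == pytest.approx(1 / 10, abs=1e-12)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(8, 8))
        s = a @ a.T
        k = 8
        # independent oracle: eigenvalues of the double-centered matrix
        c = np.eye(k) - 1.0 / k
        lam = np.linalg.eigvalsh(c @ s @ c)
        oracle = lam.sum() ** 2 / ((k - 1) * (lam**2).sum())
        assert gg_epsilon(s) == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        x = rng.normal(size=(15, 6)) @ rng.normal(size=(6, 6))
        assert gg_epsilon(np.cov(x, rowvar=False)) == pytest.approx(
            float(pg.epsilon(pd.DataFrame(x), correction="gg")), abs=1e-10
        )

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            gg_epsilon(np.arange(9.0).reshape(3, 3))


class TestMauchly:
    def test_spherical_covariance_accepts(self):
        w, chi2, df, p = mauchly_test(2.5 * np.eye(5), 20)
        assert w == pytest.approx(1.0)
        assert p == pytest.approx(1.0)
        assert df == 5 * 4 // 2 - 1

    def test_w_matches_determinant_trace_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 6))
        s = a @ a.T + np.eye(6)
        k = 6
        # oracle on an independently built orthonormal contrast basis (Helmert)
        h = np.zeros((k - 1, k))
        for i in range(k - 1):
            h[i, : i + 1] = 1.0
            h[i, i + 1] = -(i + 1)
            h[i] /= np.linalg.norm(h[i])
        t = h @ s @ h.T
        oracle = np.linalg.det(t) / (np.trace(t) / (k - 1)) ** (k - 1)
        w, _, _, _ = mauchly_test(s, 12)
        assert w == pytest.approx(oracle, abs=1e-10)

    def test_w_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        x = rng.normal(size=(14, 5)) @ rng.normal(size=(5, 5))
        res = pg.sphericity(pd.DataFrame(x))
        w, _, df, _ = mauchly_test(np.cov(x, rowvar=False), 14)
        assert w == pytest.approx(float(res.W), abs=1e-10)
        assert df == res.dof

    def test_type_one_error_calibrated_under_sphericity(self):
        rng = np.random.default_rng(5)
        n, k, reps = 20, 4, 1000
        rej = 0
        for _ in range(reps):
            x = rng.normal(size=(n, k))
            _, _, _, p = mauchly_test(np.cov(x, rowvar=False), n)
            rej += p < 0.05
        assert abs(rej / reps - 0.05) < 0.02

    def test_singular_covariance_degenerates_with_warning(self):
        v = np.random.default_rng(6).normal(size=4)
        with pytest.warns(UserWarning, match="singular"):
            w, _, _, p = mauchly_test(np.outer(v, v), 10)
        assert w == 0.0 and p == 0.0

    def test_two_levels_rejected(self):
        with pytest.raises(ValueError):
            mauchly_test(np.eye(2), 10)


class TestEstimatedMarginalMeans:
    def test_balanced_table_equals_group_mean(self):
        rng = np.random.default_rng(7)
        vals = {"a": rng.normal(30, 2, (4, 5)), "b": rng.normal(20, 2, (4, 5))}
        emm = estimated_marginal_means(rm_table(vals))
        assert emm["a"] == pytest.approx(vals["a"].mean())
        assert emm["b"] == pytest.approx(vals["b"].mean())

    def test_single_subject_group_is_subject_mean(self):
        vals = {"a": np.array([[1.0, 3.0, 5.0]]), "b": np.array([[2.0, 2.0, 2.0]])}
        emm = estimated_marginal_means(rm_table(vals))
        assert emm["a"] == pytest.approx(3.0)


class TestObservedPower:
    def test_zero_f_gives_alpha(self):
        assert observed_power(0.0, 3, 20, alpha=0.05) == pytest.approx(0.05)

    def test_monotone_and_saturating(self):
        powers = [observed_power(f, 4, 30) for f in (0.5, 1, 2, 5, 20, 200)]
        assert all(b > a for a, b in zip(powers, powers[1:]))
        assert powers[-1] > 0.9999

    def test_matches_quadrature_oracle(self):
        # oracle: P(F' > fcrit) via conditioning on the denominator chi-square
        rng = np.random.default_rng(8)
        for _ in range(5):
            f_obs = float(rng.uniform(0.5, 8))
            df1 = int(rng.integers(2, 12))
            df2 = int(rng.integers(8, 60))
            lam = f_obs * df1
            fcrit = sps.f.isf(0.05, df1, df2)
            integrand = lambda x: sps.ncx2.sf(fcrit * df1 / df2 * x, df1, lam) \
                * sps.chi2.pdf(x, df2)
            oracle, err = integrate.quad(integrand, 0, np.inf, limit=200)
            assert observed_power(f_obs, df1, df2) == pytest.approx(oracle, abs=1e-6)

    def test_invalid_dfs_rejected(self):
        with pytest.raises(ValueError):
            observed_power(1.0, 0, 10)


class TestPooledCovariance:
    def test_pooled_equals_weighted_average(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=(6, 4)), rng.normal(size=(4, 4))
        s, df = pooled_within_covariance({"a": a, "b": b})
        expected = (5 * np.cov(a, rowvar=False) + 3 * np.cov(b, rowvar=False)) / 8
        assert df == 8
        assert np.allclose(s, expected, atol=1e-12)

    def test_wide_pivot_rejects_duplicates(self):
        t = rm_table({"a": np.zeros((2, 3)), "b": np.zeros((2, 3))})
        dup = pd.concat([t, t.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError):
            _wide_by_group(dup)


class TestEpsilonProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        arrays(
            np.float64,
            (6, 4),
            elements=st.floats(-5, 5, allow_nan=False),
        )
    )
    def test_epsilon_always_within_bounds(self, a):
        """ε̂ of any PSD covariance lies in [1/(k−1), 1]."""
        s = a.T @ a + 1e-9 * np.eye(4)
        eps = gg_epsilon(s)
        assert 1.0 / 3 - 1e-12 <= eps <= 1.0 + 1e-12
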