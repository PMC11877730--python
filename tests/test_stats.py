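"""PCA, PC associations, PC-PR2, per-CpG models, rank tests, BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylxci.stats import (
    bh_fdr,
    cpg_linear_model,
    group_compare,
    pc_association,
    pca_scaled,
    pcpr2,
    wilcoxon_rank_sum,
)


def _beta(rng, n_cpgs, n_samples):
    return pd.DataFrame(
        rng.uniform(0.05, 0.95, (n_cpgs, n_samples)),
        index=[f"cg{i}" for i in range(n_cpgs)],
        columns=[f"s{i}" for i in range(n_samples)],
    )


class TestPCAScaled:
    def test_two_samples_single_component(self, rng):
        res = pca_scaled(_beta(rng, 30, 2))
        assert res.scores.shape[1] == 1
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_rank_one_data_concentrates_variance(self, rng):
        u = rng.uniform(0.1, 0.9, 40)
        v = rng.uniform(-0.2, 0.2, 10)
        beta = pd.DataFrame(
            np.clip(np.outer(u, v) + 0.5, 0, 1),
            index=[f"cg{i}" for i in range(40)],
            columns=[f"s{i}" for i in range(10)],
        )
        res = pca_scaled(beta)
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_eigendecomposition_oracle(self, rng):
        beta = _beta(rng, 50, 20)
        res = pca_scaled(beta)
        vals = beta.to_numpy()
        scaled = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1)[:, None]
        X = scaled.T
        gram = X @ X.T
        w, v = np.linalg.eigh(gram)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        k = res.scores.shape[1]
        oracle_scores = v[:, :k] * np.sqrt(np.maximum(w[:k], 0))
        assert np.allclose(np.abs(res.scores.to_numpy()), np.abs(oracle_scores), atol=1e-8)
        assert np.allclose(res.variance_fraction[:k], w[:k] / np.trace(gram), atol=1e-10)

    def test_variance_fractions_sum_to_one_full_rank(self, rng):
        res = pca_scaled(_beta(rng, 60, 12))
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)

    def test_loadings_orthonormal(self, rng):
        res = pca_scaled(_beta(rng, 40, 10))
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_sign_convention_largest_loading_positive(self, rng):
        res = pca_scaled(_beta(rng, 40, 10))
        L = res.loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_zero_variance_cpgs_dropped(self, rng):
        beta = _beta(rng, 20, 8)
        beta.iloc[0] = 0.4
        res = pca_scaled(beta)
        assert res.n_zero_variance_dropped == 1
        assert "cg0" not in res.loadings.index

    def test_missing_values_imputed_by_cpg_mean(self, rng):
        beta = _beta(rng, 20, 8)
        beta.iloc[2, 3] = np.nan
        res = pca_scaled(beta)
        assert res.n_imputed == 1
        assert np.isfinite(res.scores.to_numpy()).all()


class TestPCAssociation:
    def _pca(self, rng, n_samples=30):
        return pca_scaled(_beta(rng, 50, n_samples))

    def test_pc_equal_to_variable_gives_r2_one(self, rng):
        pca = self._pca(rng)
        samples = pd.DataFrame({"v": pca.scores["PC1"]}, index=pca.scores.index)
        out = pc_association(pca, samples, ["v"], n_components=3)
        row = out[(out["component"] == 1) & (out["variable"] == "v")].iloc[0]
        assert row["r_squared"] == pytest.approx(1.0, abs=1e-10)

    def test_two_level_factor_matches_point_biserial(self, rng):
        pca = self._pca(rng)
        grp = rng.choice(["a", "b"], len(pca.scores))
        samples = pd.DataFrame({"g": grp}, index=pca.scores.index)
        out = pc_association(pca, samples, ["g"], n_components=1)
        y = pca.scores["PC1"].to_numpy()
        x = (grp == "b").astype(float)
        r = np.corrcoef(x, y)[0, 1]
        assert out.iloc[0]["r_squared"] == pytest.approx(r**2, abs=1e-10)

    def test_constant_variable_skipped(self, rng):
        pca = self._pca(rng)
        samples = pd.DataFrame({"c": 1.0}, index=pca.scores.index)
        out = pc_association(pca, samples, ["c"])
        assert len(out) == 0

    def test_null_variable_fdr_hit_rate_controlled(self, rng):
        pca = self._pca(rng, n_samples=100)
        hits = total = 0
        for _ in range(100):
            samples = pd.DataFrame(
                {"noise": rng.normal(size=len(pca.scores))}, index=pca.scores.index
            )
            out = pc_association(pca, samples, ["noise"], n_components=10)
            hits += int(out["significant"].sum())
            total += len(out)
        assert hits / total <= 0.05


class TestPCPR2:
    def test_structural_covariate_dominates_noise_covariate(self, rng):
        n = 40
        driver = rng.normal(size=n)
        noise = rng.normal(size=n)
        loadings = rng.normal(size=60)
        vals = np.clip(0.5 + 0.15 * np.outer(loadings, driver) + rng.normal(0, 0.01, (60, n)), 0, 1)
        beta = pd.DataFrame(vals, index=[f"cg{i}" for i in range(60)], columns=[f"s{i}" for i in range(n)])
        covs = pd.DataFrame({"driver": driver, "noise": noise}, index=beta.columns)
        res = pcpr2(beta, covs)
        assert res.partial_r2_pct["driver"] > 10 * max(res.partial_r2_pct["noise"], 1e-6)
        assert res.partial_r2_pct["noise"] < 5.0

    def test_matches_direct_regression_oracle(self, rng):
        beta = _beta(rng, 50, 20)
        covs = pd.DataFrame(
            {"a": rng.normal(size=20), "b": rng.choice(["u", "v"], 20)},
            index=beta.columns,
        )
        res = pcpr2(beta, covs, variance_threshold=0.9)
        pca = pca_scaled(beta)
        cum = np.cumsum(pca.variance_fraction)
        q = int(np.searchsorted(cum, 0.9 - 1e-12) + 1)
        assert res.n_components_used == q

        a = covs["a"].to_numpy()
        b = (covs["b"] == "v").to_numpy(dtype=float)
        ones = np.ones(20)

        def rss(cols, y):
            X = np.column_stack(cols)
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ coef
            return r @ r

        lam = pca.variance_fraction[:q]
        expected = {}
        for name, keep in (("a", [ones, b]), ("b", [ones, a])):
            parts = []
            for j in range(q):
                y = pca.scores.to_numpy()[:, j]
                rss_full = rss([ones, a, b], y)
                rss_red = rss(keep, y)
                parts.append((rss_red - rss_full) / rss_red)
            expected[name] = 100 * np.average(parts, weights=lam)
        assert res.partial_r2_pct["a"] == pytest.approx(expected["a"], abs=1e-8)
        assert res.partial_r2_pct["b"] == pytest.approx(expected["b"], abs=1e-8)

    def test_threshold_one_uses_all_components(self, rng):
        beta = _beta(rng, 30, 10)
        covs = pd.DataFrame(
            {"a": rng.normal(size=10), "b": rng.normal(size=10)}, index=beta.columns
        )
        res = pcpr2(beta, covs, variance_threshold=1.0)
        assert res.n_components_used == 9  # rank of 10 centred samples

    def test_affine_rescaling_invariance(self, rng):
        beta = _beta(rng, 40, 15)
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        covs1 = pd.DataFrame({"a": a, "b": b}, index=beta.columns)
        covs2 = pd.DataFrame({"a": 100 * a - 7, "b": b}, index=beta.columns)
        r1 = pcpr2(beta, covs1)
        r2 = pcpr2(beta, covs2)
        assert r1.partial_r2_pct["a"] == pytest.approx(r2.partial_r2_pct["a"], abs=1e-8)

    def test_collinear_covariates_rejected_naming_pair(self, rng):
        beta = _beta(rng, 30, 12)
        a = rng.normal(size=12)
        covs = pd.DataFrame({"a": a, "a_copy": a * 2.0}, index=beta.columns)
        with pytest.raises(ValueError, match="a.*a_copy"):
            pcpr2(beta, covs)


class TestCpgLinearModel:
    def _samples(self, rng, n):
        return pd.DataFrame(
            {"gestational_age": rng.uniform(8, 42, n)},
            index=[f"s{i}" for i in range(n)],
        )

    def test_constant_beta_gives_zero_slope(self, rng):
        samples = self._samples(rng, 20)
        beta = pd.DataFrame(0.5, index=["cg0"], columns=samples.index)
        out = cpg_linear_model(beta, samples)
        assert out.iloc[0]["slope"] == 0.0
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_recovers_known_slope(self, rng):
        n = 50
        samples = self._samples(rng, n)
        ga = samples["gestational_age"].to_numpy()
        beta = pd.DataFrame(
            np.clip(0.3 + 0.01 * (ga - ga.mean()) + rng.normal(0, 0.001, (5, n)), 0, 1),
            index=[f"cg{i}" for i in range(5)],
            columns=samples.index,
        )
        out = cpg_linear_model(beta, samples)
        assert np.allclose(out["slope"], 0.01, atol=0.002)

    def test_slope_estimates_unbiased(self, rng):
        n, m, true_slope = 100, 2000, 0.005
        samples = self._samples(rng, n)
        ga = samples["gestational_age"].to_numpy()
        beta = pd.DataFrame(
            np.clip(0.5 + true_slope * (ga - ga.mean()) + rng.normal(0, 0.02, (m, n)), 0, 1),
            index=[f"cg{i}" for i in range(m)],
            columns=samples.index,
        )
        out = cpg_linear_model(beta, samples)
        bias = out["slope"].mean() - true_slope
        assert abs(bias) < 0.1 * true_slope

    def test_complete_case_handling_matches_subset_fit(self, rng):
        n = 30
        samples = self._samples(rng, n)
        ga = samples["gestational_age"].to_numpy()
        vals = np.clip(0.4 + 0.008 * (ga - ga.mean()) + rng.normal(0, 0.01, n), 0, 1)
        vals_missing = vals.copy()
        vals_missing[:5] = np.nan
        beta = pd.DataFrame([vals_missing], index=["cg0"], columns=samples.index)
        out = cpg_linear_model(beta, samples)
        sub = pd.DataFrame([vals[5:]], index=["cg0"], columns=samples.index[5:])
        expected = cpg_linear_model(sub, samples.iloc[5:])
        assert out.iloc[0]["slope"] == pytest.approx(expected.iloc[0]["slope"], abs=1e-12)
        assert out.iloc[0]["p_value"] == pytest.approx(expected.iloc[0]["p_value"], abs=1e-12)

    def test_adjustment_for_confounder_removes_false_effect(self, rng):
        n = 80
        ga = rng.uniform(8, 42, n)
        confounder = ga / 42 + rng.normal(0, 0.05, n)
        samples = pd.DataFrame(
            {"gestational_age": ga, "conf": confounder}, index=[f"s{i}" for i in range(n)]
        )
        beta = pd.DataFrame(
            np.clip(0.3 + 0.3 * confounder + rng.normal(0, 0.01, (10, n)), 0, 1),
            index=[f"cg{i}" for i in range(10)],
            columns=samples.index,
        )
        unadj = cpg_linear_model(beta, samples)
        adj = cpg_linear_model(beta, samples, adjustment=["conf"])
        assert unadj["slope"].abs().mean() > 3 * adj["slope"].abs().mean()

    def test_rank_deficient_design_lists_aliased_columns(self, rng):
        samples = self._samples(rng, 20)
        samples["twin"] = samples["gestational_age"] * 2
        beta = pd.DataFrame(
            rng.uniform(0, 1, (3, 20)), index=["a", "b", "c"], columns=samples.index
        )
        with pytest.raises(ValueError, match="aliased"):
            cpg_linear_model(beta, samples, adjustment=["twin"])

    def test_too_few_predictor_levels_rejected(self, rng):
        samples = pd.DataFrame(
            {"gestational_age": [38.0, 40.0] * 5}, index=[f"s{i}" for i in range(10)]
        )
        beta = pd.DataFrame(rng.uniform(0, 1, (2, 10)), index=["a", "b"], columns=samples.index)
        with pytest.raises(ValueError, match="distinct"):
            cpg_linear_model(beta, samples)


class TestGroupCompare:
    def test_shifted_distributions_strongly_significant(self):
        rng = np.random.default_rng(5)
        values = pd.Series(
            np.concatenate([rng.normal(0.3, 0.02, 12), rng.normal(0.4, 0.02, 12)]),
            index=[f"s{i}" for i in range(24)],
        )
        groups = pd.Series(["placenta"] * 12 + ["muscle"] * 12, index=values.index)
        out = group_compare(values, groups, "placenta")
        assert out.iloc[0]["fdr"] < 0.0001
        assert out.iloc[0]["stars"] == "****"

    def test_null_groups_rarely_significant(self):
        sig = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = pd.Series(rng.normal(0.5, 0.05, 24), index=[f"s{i}" for i in range(24)])
            groups = pd.Series(["a"] * 12 + ["b"] * 12, index=values.index)
            out = group_compare(values, groups, "a")
            sig += int(out.iloc[0]["p_value"] < 0.05)
        assert sig <= 2  # p >= 0.05 in >= 90% of null replicates

    def test_exact_rank_sum_small_groups(self):
        # 3+3 with clean separation: two-sided exact p = 2/20 = 0.1
        p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.1)

    def test_empty_reference_rejected(self):
        values = pd.Series([1.0, 2.0], index=["a", "b"])
        groups = pd.Series(["g1", "g1"], index=values.index)
        with pytest.raises(ValueError, match="reference"):
            group_compare(values, groups, "missing")


class TestBhFdr:
    def test_hand_computed_step_up(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_mixed_example(self):
        # step-up by hand: sorted (0.005, 0.04, 0.04, 0.8) -> (0.02, 0.0533.., 0.0533.., 0.8)
        out = bh_fdr([0.04, 0.005, 0.8, 0.04])
        assert np.allclose(out, [0.16 / 3, 0.02, 0.8, 0.16 / 3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_dominates_input_and_preserves_order(self, ps):
        out = bh_fdr(ps)
        assert np.all(out >= np.asarray(ps) - 1e-15)
        assert np.all(out <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(out[order]) >= -1e-15)  # monotone in sorted order
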