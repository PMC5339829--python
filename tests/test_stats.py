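"""Statistical machinery: t-tests, FDR, covariates, permutation, Spearman."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fcnet.connectivity import ConnectivityMatrix
from fcnet.stats import (
    auc_group_inference,
    bh_fdr,
    covariate_adjust,
    edgewise_group_test,
    export_brainnet,
    permutation_group_test,
    spearman_clinical,
    two_sample_t,
    two_sample_t_from_stats,
)


class TestTwoSampleT:
    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1.2, 25)
        from scipy.stats import ttest_ind

        t, p = two_sample_t(a, b)
        ref = ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_from_summary_stats(self):
        # pooled-variance t from printed means/SDs (n=42 per group)
        t, _ = two_sample_t_from_stats(69.40, 26.84, 42, 20.29, 15.71, 42)
        assert t == pytest.approx(10.24, abs=0.05)
        t, _ = two_sample_t_from_stats(12.60, 7.63, 42, 2.17, 2.57, 42)
        assert t == pytest.approx(8.40, abs=0.05)

    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = two_sample_t(a, a.copy())
        assert t == 0.0 and p == 1.0


class TestBhFdr:
    def test_hand_oracle(self):
        # p = (0.01, 0.02, 0.04, 0.5): BH at q=0.05 rejects the first two
        p = np.array([0.01, 0.02, 0.04, 0.5])
        q = bh_fdr(p)
        assert (q < 0.05).sum() == 2

    def brute_bh(self, p, alpha):
        m = len(p)
        order = np.argsort(p)
        ranked = p[order]
        k = 0
        for i in range(m):
            if ranked[i] <= (i + 1) / m * alpha:
                k = i + 1
        reject = np.zeros(m, dtype=bool)
        reject[order[:k]] = True
        return reject

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 11))
        p = rng.random(m)
        q = bh_fdr(p)
        for alpha in (0.01, 0.05, 0.1, 0.25):
            assert np.array_equal(q <= alpha, self.brute_bh(p, alpha))

    def test_monotone_in_p_order(self):
        rng = np.random.default_rng(99)
        p = rng.random(30)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.5]))


class TestCovariateAdjust:
    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(1)
        n = 60
        cov = pd.DataFrame({"age": rng.uniform(18, 60, n),
                            "sex": rng.choice(["f", "m"], n)})
        y = 0.5 * cov["age"].to_numpy() + rng.normal(size=n)
        resid = covariate_adjust(y, cov)
        assert abs(np.corrcoef(resid, cov["age"])[0, 1]) < 1e-10
        assert abs(resid.mean()) < 1e-10

    def test_constant_covariate_mean_centres(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        cov = pd.DataFrame({"c": [5.0, 5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning):
            resid = covariate_adjust(y, cov)
        assert np.allclose(resid, y - y.mean())


class TestEdgewise:
    def _cohort(self, n_per_group=8, n=12, delta=0.0, seed=0):
        rng = np.random.default_rng(seed)
        mats, groups = [], []
        for g, label in ((0, "patient"), (1, "control")):
            for _ in range(n_per_group):
                z = np.abs(rng.normal(0.3, 0.1, (n, n)))
                if g == 0:
                    z[0, 1] = z[1, 0] = z[0, 1] + delta
                z = (z + z.T) / 2
                np.fill_diagonal(z, 0)
                mats.append(ConnectivityMatrix(z_values=z))
                groups.append(label)
        return mats, np.array(groups)

    def test_one_test_per_unique_pair(self):
        mats, groups = self._cohort(n=12)
        res = edgewise_group_test(mats, groups)
        assert len(res) == 12 * 11 // 2
        assert {"i", "j", "i_label", "j_label", "t", "p", "q", "direction"} <= set(res.columns)

    def test_planted_edge_has_smallest_q(self):
        mats, groups = self._cohort(n=10, delta=0.6, seed=3)
        res = edgewise_group_test(mats, groups)
        best = res.sort_values("q").iloc[0]
        assert {int(best["i"]), int(best["j"])} == {0, 1}
        assert best["direction"] == 1

    def test_brainnet_export(self, tmp_path):
        mats, groups = self._cohort(n=10, delta=0.8, seed=4)
        res = edgewise_group_test(mats, groups)
        n_sig = export_brainnet(res, mats[0].roi_labels,
                                tmp_path / "x.node", tmp_path / "x.edge")
        node_lines = (tmp_path / "x.node").read_text().strip().splitlines()
        assert len(node_lines) == 10
        edge = np.loadtxt(tmp_path / "x.edge")
        assert edge.shape == (10, 10)
        if n_sig:
            sizes = np.array([float(l.split()[4]) for l in node_lines])
            assert sizes.sum() == 2 * n_sig


class TestPermutation:
    def test_null_p_uniformish(self):
        rng = np.random.default_rng(5)
        ps = []
        groups = np.array(["patient"] * 12 + ["control"] * 12)
        for rep in range(60):
            vals = rng.normal(size=24)
            res = permutation_group_test(vals, groups, n_perm=199, seed=rep)
            ps.append(res.p_value)
        ps = np.array(ps)
        assert ps.min() >= 1 / 200
        assert 0.25 < ps.mean() < 0.75

    def test_detects_shift(self):
        rng = np.random.default_rng(6)
        vals = np.concatenate([rng.normal(1.5, 1, 15), rng.normal(0, 1, 15)])
        groups = np.array(["patient"] * 15 + ["control"] * 15)
        res = permutation_group_test(vals, groups, n_perm=999, seed=0)
        assert res.observed_difference > 0
        assert res.p_value < 0.05

    def test_add_one_floor(self):
        vals = np.concatenate([np.full(10, 10.0) + np.arange(10) * 1e-6,
                               np.zeros(10) + np.arange(10) * 1e-6])
        groups = np.array(["patient"] * 10 + ["control"] * 10)
        res = permutation_group_test(vals, groups, n_perm=99, seed=1)
        assert res.p_value == pytest.approx(1 / 100)

    def test_covariate_adjustment_removes_confound(self):
        # group difference entirely explained by age
        rng = np.random.default_rng(7)
        age = np.concatenate([rng.uniform(40, 60, 20), rng.uniform(20, 40, 20)])
        vals = 0.1 * age + rng.normal(0, 0.3, 40)
        groups = np.array(["patient"] * 20 + ["control"] * 20)
        cov = pd.DataFrame({"age": age})
        raw = permutation_group_test(vals, groups, n_perm=499, seed=2)
        adj = permutation_group_test(vals, groups, covariates=cov, n_perm=499, seed=2)
        assert raw.p_value < 0.05
        assert adj.p_value > 0.05

    def test_schemes_agree_on_clean_signal(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.normal(2, 1, 15), rng.normal(0, 1, 15)])
        groups = np.array(["patient"] * 15 + ["control"] * 15)
        cov = pd.DataFrame({"age": rng.uniform(20, 60, 30)})
        p1 = permutation_group_test(vals, groups, covariates=cov, n_perm=999,
                                    seed=3, scheme="simple").p_value
        p2 = permutation_group_test(vals, groups, covariates=cov, n_perm=999,
                                    seed=3, scheme="freedman-lane").p_value
        assert p1 < 0.05 and p2 < 0.05


class TestAucGroupInference:
    def test_global_and_nodal_families(self):
        rng = np.random.default_rng(9)
        groups = np.array(["patient"] * 10 + ["control"] * 10)
        aucs = []
        for k in range(20):
            aucs.append({
                "aLp": rng.normal(2.0 + (0.5 if k < 10 else 0.0), 0.2),
                "aCp": rng.normal(),
                "anodalDeg": rng.normal(size=5),
            })
        res = auc_group_inference(aucs, groups, n_perm=499, seed=0,
                                  roi_labels=[f"R{i}" for i in range(5)])
        by_metric = {}
        for r in res:
            by_metric.setdefault(r.metric_name, []).append(r)
        assert len(by_metric["aLp"]) == 1
        assert by_metric["aLp"][0].p_value < 0.05
        # globals report q = p (no FDR family)
        assert by_metric["aLp"][0].q_value == by_metric["aLp"][0].p_value
        nodal = by_metric["anodalDeg"]
        assert len(nodal) == 5
        assert {r.node for r in nodal} == {f"R{i}" for i in range(5)}


class TestSpearman:
    def test_hand_oracle(self):
        rho, _ = spearman_clinical([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_matches_scipy_large_n(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(10)
        x, y = rng.normal(size=25), rng.normal(size=25)
        rho, p = spearman_clinical(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_small_n_enumeration(self):
        # for n=5, exact two-sided p of a perfect ranking is 2/5! = 1/60
        rho, p = spearman_clinical([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)

    def test_bonferroni_caps_at_one(self):
        _, p = spearman_clinical([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], bonferroni_m=50)
        assert p == 1.0
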