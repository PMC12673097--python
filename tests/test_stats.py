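"""Wilks'-Lambda MANOVA and midrank Spearman correlation."""

import numpy as np
import pytest
from scipy import stats as sps

import sitpheno as sp


def wilks_oracle(X, labels):
    """Independent accumulation of within/between cross-product matrices,
    element by element, then the determinant ratio."""
    X = np.asarray(X, float)
    n, p = X.shape
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for lab in set(labels):
        sub = X[np.asarray(labels) == lab]
        mu = sub.mean(axis=0)
        for row in sub:
            d = row - mu
            for i in range(p):
                for j in range(p):
                    W[i, j] += d[i] * d[j]
        dm = mu - grand
        for i in range(p):
            for j in range(p):
                B[i, j] += len(sub) * dm[i] * dm[j]
    return np.linalg.det(W) / np.linalg.det(W + B)


class TestManova:
    def test_identical_group_means_lambda_one(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(6, 2))
        X = np.vstack([base, base])  # two groups, identical rows
        labels = ["a"] * 6 + ["b"] * 6
        res = sp.manova_wilks(X, labels)
        assert res.wilks_lambda == pytest.approx(1.0)
        assert res.f_stat == pytest.approx(0.0, abs=1e-10)

    def test_matches_det_ratio_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            X = rng.normal(size=(15, 2))
            labels = np.repeat(["a", "b", "c"], 5)
            X[labels == "b"] += rng.normal(0, 1, 2)
            res = sp.manova_wilks(X, labels)
            assert res.wilks_lambda == pytest.approx(
                wilks_oracle(X, labels), abs=1e-9
            )

    def test_matches_statsmodels(self):
        """Independent library cross-check of Λ, F, dfs and p."""
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(6)
        X = rng.normal(size=(18, 2))
        labels = np.repeat(["g1", "g2", "g3"], 6)
        X[labels == "g3"] += [1.0, -0.5]
        res = sp.manova_wilks(X, labels)
        import pandas as pd
        df = pd.DataFrame({"y1": X[:, 0], "y2": X[:, 1], "g": labels})
        mv = MANOVA.from_formula("y1 + y2 ~ g", data=df)
        tbl = mv.mv_test().results["g"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            tbl.loc["Wilks' lambda", "Value"], abs=1e-9
        )
        assert res.f_stat == pytest.approx(
            tbl.loc["Wilks' lambda", "F Value"], rel=1e-6
        )
        assert res.p == pytest.approx(tbl.loc["Wilks' lambda", "Pr > F"], abs=1e-9)

    def test_two_group_case_reduces_to_hotelling(self):
        """With two groups Wilks' F equals the two-sample Hotelling T²
        F-statistic."""
        rng = np.random.default_rng(12)
        X = rng.normal(size=(20, 2))
        labels = np.repeat(["a", "b"], 10)
        X[labels == "b"] += [0.8, 0.3]
        res = sp.manova_wilks(X, labels)
        xa, xb = X[:10], X[10:]
        na, nb, p = 10, 10, 2
        Sp = ((na - 1) * np.cov(xa.T) + (nb - 1) * np.cov(xb.T)) / (na + nb - 2)
        d = xa.mean(0) - xb.mean(0)
        t2 = (na * nb) / (na + nb) * d @ np.linalg.inv(Sp) @ d
        f_hotelling = (na + nb - p - 1) / (p * (na + nb - 2)) * t2
        assert res.f_stat == pytest.approx(f_hotelling, rel=1e-9)

    def test_affine_feature_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 2))
        labels = np.repeat(["a", "b"], 6)
        X[labels == "b"] += 0.5
        res1 = sp.manova_wilks(X, labels)
        X2 = X.copy()
        X2[:, 0] = 100.0 * X2[:, 0] - 3.0
        res2 = sp.manova_wilks(X2, labels)
        assert res2.wilks_lambda == pytest.approx(res1.wilks_lambda, abs=1e-9)
        assert res2.p == pytest.approx(res1.p, abs=1e-9)

    def test_precondition_errors(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        with pytest.raises(ValueError, match="2 groups"):
            sp.manova_wilks(X, ["a"] * 6)
        with pytest.raises(ValueError, match="fewer than 2"):
            sp.manova_wilks(X, ["a", "a", "a", "a", "a", "b"])

    def test_singular_within_matrix_named(self):
        X = np.column_stack([np.ones(8), np.random.default_rng(0).normal(size=8)])
        labels = np.repeat(["a", "b"], 4)
        with pytest.raises(ValueError, match="column 0"):
            sp.manova_wilks(X, labels)


def spearman_oracle(x, y):
    """Explicit rank assignment (ties → mean rank) then textbook Pearson."""
    def ranks(v):
        v = np.asarray(v, float)
        out = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            out[i] = less + (equal + 1) / 2.0
        return out

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


class TestSpearman:
    def test_monotone_is_one(self):
        x = np.array([0.1, 0.5, 1.2, 2.0, 3.3])
        y = np.array([1, 2, 3, 4, 5])
        res = sp.spearman_rho(x, y)
        assert res.rho == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_antitone_is_minus_one(self):
        x = np.array([3.3, 2.0, 1.2, 0.5, 0.1])
        y = np.array([1, 2, 3, 4, 5])
        assert sp.spearman_rho(x, y).rho == pytest.approx(-1.0)

    def test_ties_match_rank_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            x = rng.uniform(0, 3, 20).round(1)  # plenty of ties
            y = rng.integers(1, 6, 20)
            res = sp.spearman_rho(x, y)
            assert res.rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)
            assert res.n == 20

    def test_matches_scipy(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=30)
        y = rng.integers(1, 6, 30)
        res = sp.spearman_rho(x, y)
        ref_rho, ref_p = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref_rho, abs=1e-12)
        assert res.p == pytest.approx(ref_p, rel=1e-9)

    def test_invariant_under_monotone_transform_of_x(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0.1, 5.0, 25)
        y = rng.integers(1, 6, 25)
        r1 = sp.spearman_rho(x, y).rho
        r2 = sp.spearman_rho(np.exp(x), y).rho
        assert r2 == pytest.approx(r1, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="n >= 3"):
            sp.spearman_rho([1.0, 2.0], [1, 2])
        with pytest.raises(ValueError, match="range"):
            sp.spearman_rho([1.0, 2.0, 3.0], [1, 2, 9])
        with pytest.raises(ValueError, match="zero variance"):
            sp.spearman_rho([1.0, 2.0, 3.0], [2, 2, 2])
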