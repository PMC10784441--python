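"""Screening, PAM consensus clustering and LASSO selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ptrarad import select
from ptrarad.select import (
    choose_k_and_medoids,
    consensus_cluster,
    feature_auc,
    feature_pvalue,
    lasso_select,
    pam,
    spearman_distance,
    univariate_screen,
    zscore,
)


class TestZscore:
    def test_basic_column(self):
        z = zscore(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 5.0]}))
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=0), 1.0, atol=1e-12)

    def test_idempotent(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)), columns=list("abc"))
        z1 = zscore(df)
        z2 = zscore(z1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)

    def test_zero_variance_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning):
            z = zscore(df)
        assert list(z.columns) == ["a"]

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            zscore(pd.DataFrame({"x": [1.0, 1.0], "y": [2.0, 2.0]}))


class TestScreen:
    def test_exact_mann_whitney_small_groups(self):
        # U = 0 for fully separated triples; exact two-sided P = 2 * 1/20 = 0.1
        test, p = feature_pvalue([1, 2, 3], [4, 5, 6], force="mannwhitney")
        assert p == pytest.approx(0.1)

    def test_small_class_routes_to_mannwhitney(self):
        test, _ = feature_pvalue([1.0, 2.0], [3.0, 4.0, 5.0])
        assert test == "mannwhitney"

    def test_label_feature_is_retained(self):
        rng = np.random.default_rng(0)
        labels = np.array([1] * 18 + [0] * 34)
        df = pd.DataFrame(
            {
                "oracle": labels + rng.normal(0, 0.01, 52),
                "noise": rng.normal(size=52),
            }
        )
        screen = univariate_screen(df, labels, compute_auc=False)
        assert screen.loc["oracle", "p"] < 1e-4
        assert screen.loc["oracle", "retained"]
        assert screen.loc["oracle", "significant"]

    def test_retained_superset_of_significant(self):
        rng = np.random.default_rng(1)
        labels = np.array([1] * 10 + [0] * 14)
        df = pd.DataFrame(rng.normal(size=(24, 30)), columns=[f"f{i}" for i in range(30)])
        screen = univariate_screen(df, labels, compute_auc=False)
        assert (screen["significant"] <= screen["retained"]).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            univariate_screen(pd.DataFrame({"a": [1.0, 2.0]}), np.array([1, 1]))


class TestFeatureAUC:
    def test_perfect_separation(self):
        auc, _ = feature_auc(np.r_[np.zeros(5), np.ones(5)], np.r_[np.zeros(5), np.ones(5)], n_boot=50)
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = feature_auc(np.ones(10), np.r_[np.zeros(5), np.ones(5)], n_boot=50)
        assert auc == 0.5

    def test_negation_symmetry(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=20)
        y = rng.integers(0, 2, 20)
        y[:2], y[-2:] = 0, 1
        a1, _ = feature_auc(v, y, n_boot=10)
        a2, _ = feature_auc(-v, y, n_boot=10)
        assert a1 == pytest.approx(1 - a2)


def _block_table(n=60, seed=0):
    """Two feature blocks driven by independent latents (|rho| = 1 within)."""
    rng = np.random.default_rng(seed)
    g1, g2 = rng.normal(size=n), rng.normal(size=n)
    return pd.DataFrame(
        {
            "a1": g1,
            "a2": 2 * g1 + 1,
            "a3": -(g1**3),
            "b1": g2,
            "b2": np.exp(g2),
            "b3": -5 * g2,
        }
    )


class TestPAM:
    def test_planted_blocks_recovered(self):
        df = _block_table()
        dist = spearman_distance(df)
        _, assign = pam(dist, 2)
        assert len(set(assign[:3])) == 1
        assert len(set(assign[3:])) == 1
        assert assign[0] != assign[3]

    def test_medoid_optimality_small_exhaustive(self):
        # PAM's total within-cluster distance matches the exhaustive optimum
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 2))
        dist = np.abs(pts[:, None, :] - pts[None, :, :]).sum(-1)
        medoids, assign = pam(dist, 2)
        cost = dist[medoids].min(axis=0).sum()
        best = min(
            dist[list(combo)].min(axis=0).sum() for combo in itertools.combinations(range(7), 2)
        )
        assert cost == pytest.approx(best)


class TestConsensus:
    def test_planted_blocks_consensus_one(self):
        df = _block_table()
        res = consensus_cluster(df, k=2, resamples=100, seed=0)
        blocks = {res.assignment[f] for f in ("a1", "a2", "a3")}
        assert len(blocks) == 1
        assert {res.assignment[f] for f in ("b1", "b2", "b3")} != blocks
        assert all(v == pytest.approx(1.0) for v in res.consensus.values())

    def test_k_equals_feature_count(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        res = consensus_cluster(df, k=5, resamples=20, seed=0)
        assert sorted(res.medoids) == sorted(df.columns)
        assert all(v == 1.0 for v in res.consensus.values())

    def test_column_permutation_invariance(self):
        df = _block_table()
        shuffled = df[["b2", "a3", "b1", "a1", "b3", "a2"]]
        r1 = consensus_cluster(df, 2, resamples=50, seed=1)
        r2 = consensus_cluster(shuffled, 2, resamples=50, seed=1)
        same1 = r1.assignment["a1"] == r1.assignment["a2"]
        same2 = r2.assignment["a1"] == r2.assignment["a2"]
        assert same1 and same2
        assert (r1.assignment["a1"] == r1.assignment["b1"]) == (
            r2.assignment["a1"] == r2.assignment["b1"]
        )

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            consensus_cluster(_block_table(), k=7)

    def test_monotone_transform_invariance(self):
        # Spearman-based distances are unchanged by monotone feature transforms
        df = _block_table()
        transformed = df.copy()
        transformed["a1"] = np.exp(df["a1"])
        transformed["b2"] = df["b2"] ** 3
        np.testing.assert_allclose(
            spearman_distance(df), spearman_distance(transformed), atol=1e-12
        )


class TestChooseK:
    def test_tight_correlation_accepts_k2(self):
        rng = np.random.default_rng(4)
        g = rng.normal(size=80)
        h = rng.normal(size=80)
        df = pd.DataFrame(
            {
                "x1": g,
                "x2": g + rng.normal(0, 0.1, 80),
                "y1": h,
                "y2": h + rng.normal(0, 0.1, 80),
            }
        )
        res = choose_k_and_medoids(df, resamples=50, seed=0)
        assert res.k == 2

    def test_orphan_feature_becomes_singleton_medoid(self):
        rng = np.random.default_rng(5)
        g = rng.normal(size=100)
        df = pd.DataFrame(
            {
                "x1": g,
                "x2": g + rng.normal(0, 0.05, 100),
                "x3": -g + rng.normal(0, 0.05, 100),
                "orphan": rng.normal(size=100),
            }
        )
        res = choose_k_and_medoids(df, resamples=50, seed=0)
        assert "orphan" in res.medoids
        assert res.assignment["orphan"] not in {
            res.assignment["x1"],
            res.assignment["x2"],
            res.assignment["x3"],
        }


class TestLasso:
    def _planted(self, seed=0, n=52, noise_features=10):
        rng = np.random.default_rng(seed)
        labels = np.array([1] * 18 + [0] * 34)
        rng.shuffle(labels)
        planted = labels * 1.5 + rng.normal(0, 1.0, n)  # AUC ~ 0.85
        data = {"planted": planted}
        for i in range(noise_features):
            data[f"noise{i}"] = rng.normal(size=n)
        return pd.DataFrame(data), labels

    def test_infinite_strength_selects_nothing(self):
        df, y = self._planted()
        path = lasso_select(df, y, c_grid=np.array([1e-6]), cv_folds=5)
        assert path.selected == []

    def test_weak_penalty_matches_unpenalized_support(self):
        df, y = self._planted()
        path = lasso_select(df, y, c_grid=np.array([1e6]), cv_folds=5)
        assert "planted" in path.selected
        assert len(path.selected) == df.shape[1]  # essentially no shrinkage

    def test_planted_feature_recovered(self):
        df, y = self._planted(seed=11)
        path = lasso_select(df, y, seed=0)
        assert "planted" in path.selected
        assert path.selected[0] == "planted"  # largest |coefficient|
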