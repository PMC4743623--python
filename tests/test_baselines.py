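"""Reference methods: MANOVA cross-checked against statsmodels, iST rule, ROC, FDR calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.multivariate.manova import MANOVA

from mthess.baselines import (
    ClassificationTable,
    ScoreMatrix,
    classification_table,
    hotspot_size_summary,
    ist_hess_scores,
    manova_pair_test,
    manova_scores,
    roc_auc,
    roc_points,
    true_fdr_threshold,
)
from mthess.simulate import SimConfig, SimTruth, simulate_dataset


def make_truth(gamma, labels=None):
    gamma = np.asarray(gamma, dtype=bool)
    labels = np.asarray(labels, dtype=np.int8) if labels is not None else gamma.astype(np.int8) * 3
    return SimTruth(gamma, np.zeros(gamma.shape), labels, np.array([], dtype=int), (), [])


class TestMANOVA:
    @given(st.integers(0, 30))
    def test_matches_statsmodels(self, seed):
        """Wilks p-value equals the statsmodels MANOVA Wilks row."""
        rng = np.random.default_rng(seed)
        n, r = 20, 3
        x = (rng.random(n) < 0.5).astype(float)
        if x.std() == 0:
            x[0] = 1 - x[0]
        Y = rng.standard_normal((n, r)) + 0.4 * x[:, None]
        p_mine = manova_pair_test(Y, x)
        df = pd.DataFrame(Y, columns=["y1", "y2", "y3"])
        df["x"] = x
        res = MANOVA.from_formula("y1 + y2 + y3 ~ x", data=df).mv_test()
        tab = res.results["x"]["stat"]
        p_sm = float(tab.loc["Wilks' lambda", "Pr > F"])
        assert p_mine == pytest.approx(p_sm, rel=1e-6, abs=1e-12)

    def test_vectorized_matches_loop(self):
        rng = np.random.default_rng(1)
        n, p, q, r = 15, 6, 4, 2
        X = (rng.random((n, p)) < 0.5).astype(float)
        X[:, 0] = np.arange(n) % 2  # ensure variability
        stacks = rng.standard_normal((q, n, r))
        sc = manova_scores(X, stacks)
        for k in range(q):
            for j in range(p):
                if X[:, j].std() == 0:
                    continue
                pv = manova_pair_test(stacks[k], X[:, j])
                assert sc.values[k, j] == pytest.approx(-np.log10(max(pv, 1e-300)), rel=1e-8)

    def test_constant_marker_rejected(self):
        Y = np.random.default_rng(0).standard_normal((10, 2))
        with pytest.raises(ValueError):
            manova_pair_test(Y, np.ones(10))


class TestIST:
    @given(st.integers(0, 50))
    def test_min_rule_equivalence(self, seed):
        """thresholding the min equals the all-conditions-exceed rule, all thresholds."""
        rng = np.random.default_rng(seed)
        mats = [rng.random((5, 7)) for _ in range(3)]
        combined = ist_hess_scores(mats).values
        thresholds = np.unique(np.concatenate([m.ravel() for m in mats] + [np.array([0.0, 1.0])]))
        for t in thresholds:
            all_exceed = np.logical_and.reduce([m >= t for m in mats])
            assert np.array_equal(combined >= t, all_exceed)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ist_hess_scores([np.zeros((2, 2)), np.zeros((3, 2))])
        with pytest.raises(ValueError):
            ist_hess_scores([np.zeros((2, 2))])


class TestROC:
    def test_perfect_and_reverse_scores(self):
        truth = make_truth([[1, 0, 0], [0, 0, 1]])
        perfect = ScoreMatrix(truth.gamma_true.astype(float))
        assert roc_auc(perfect, truth) == pytest.approx(1.0)
        reverse = ScoreMatrix(1.0 - truth.gamma_true.astype(float))
        assert roc_auc(reverse, truth) == pytest.approx(0.0)

    def test_roc_endpoints_monotone(self):
        rng = np.random.default_rng(2)
        truth = make_truth(rng.random((4, 6)) < 0.3)
        sc = ScoreMatrix(rng.random((4, 6)))
        fpr, tpr = roc_points(sc, truth)
        assert fpr[0] == 0.0 and fpr[-1] == 1.0 and tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_lower_is_stronger_orientation(self):
        truth = make_truth([[1, 0, 0, 0]])
        pvals = ScoreMatrix(np.array([[0.001, 0.5, 0.9, 0.7]]), higher_is_stronger=False)
        assert roc_auc(pvals, truth) == pytest.approx(1.0)


class TestTrueFDR:
    def test_hand_example(self):
        """scores 9,8,7,6 with truth 1,1,0,1: FDR by prefix is
        0, 0, 1/3, 1/4 — at level .2 only the top-2 set passes (threshold 8);
        at level .25 the most permissive passing set is all four (threshold 6)."""
        truth = make_truth([[1, 1, 0, 1]])
        sc = ScoreMatrix(np.array([[9.0, 8.0, 7.0, 6.0]]))
        assert true_fdr_threshold(sc, truth, 0.20) == pytest.approx(8.0)
        assert true_fdr_threshold(sc, truth, 0.25) == pytest.approx(6.0)

    def test_tie_group_atomicity(self):
        truth = make_truth([[1, 0, 1, 0]])
        sc = ScoreMatrix(np.array([[5.0, 5.0, 5.0, 1.0]]))  # tied group has FDR 1/3
        assert true_fdr_threshold(sc, truth, 0.2) is None
        assert true_fdr_threshold(sc, truth, 0.4) == pytest.approx(5.0)

    @given(st.integers(0, 100))
    def test_realized_fdr_at_threshold(self, seed):
        rng = np.random.default_rng(seed)
        gamma = rng.random((4, 8)) < 0.3
        if not gamma.any():
            gamma[0, 0] = True
        truth = make_truth(gamma)
        sc = ScoreMatrix(rng.random((4, 8)) + gamma)
        thr = true_fdr_threshold(sc, truth, 0.3)
        if thr is not None:
            called = sc.values >= thr
            fp = int((called & ~gamma).sum())
            tp = int((called & gamma).sum())
            assert tp + fp > 0
            assert fp / (tp + fp) <= 0.3


class TestTables:
    def test_oracle_scores_give_perfect_table(self):
        """perfect scores recover the class sizes exactly."""
        cfg = SimConfig.scaled_down(seed=8)
        X, Y, truth = simulate_dataset(cfg)
        oracle = ScoreMatrix(truth.gamma_true.astype(float))
        tab = classification_table(oracle, truth, 0.10)
        assert tab.counts[1].tolist() == [0.0, 5.0, 5.0, 40.0]
        assert tab.counts.sum() == truth.gamma_true.size
        # column sums are the class sizes regardless of the scores
        assert tab.counts.sum(axis=0).tolist() == [50 * 300 - 50, 5.0, 5.0, 40.0]

    def test_hotspot_size_summary_oracle(self):
        cfg = SimConfig.scaled_down(seed=8)
        X, Y, truth = simulate_dataset(cfg)
        oracle = ScoreMatrix(truth.gamma_true.astype(float))
        hs = hotspot_size_summary(oracle, truth, 0.10)
        for size, mean_called in hs.items():
            assert mean_called >= size  # cis-other pairs can add to a hotspot column
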