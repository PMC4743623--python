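"""Posterior summaries: MPPI, Bayesian FDR, calls, hotspots, best models, adequacy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mthess.likelihood import HyperParams, MarginalLikelihoodEngine
from mthess.postprocess import (
    NO_CALLS,
    association_calls,
    bayes_fdr,
    best_model,
    compute_mppi,
    hotspot_table,
    loo_checking_function,
    renormalized_model_probs,
    threshold_for_bfdr,
)
from mthess.sampler import PosteriorTrace, SamplerConfig, run_sampler

from conftest import make_small_fixture


def make_trace(counts, n_rec, visited=None, g=None, omega=None, rho=None):
    counts = np.asarray(counts, dtype=float)
    q, p = counts.shape
    return PosteriorTrace(
        gamma_inclusion_counts=counts,
        n_recorded=n_rec,
        g_samples=np.asarray(g if g is not None else [5.0, 6.0]),
        omega_samples=np.asarray(omega if omega is not None else [[0.2] * q]),
        rho_samples=np.asarray(rho if rho is not None else [[1.0] * p]),
        visited_models=visited if visited is not None else [dict() for _ in range(q)],
        acceptance_stats={},
        temperatures=np.array([1.0, 2.0, 4.0]),
    )


class TestBayesFDR:
    def test_hand_computed(self):
        """bFDR by hand: pi = (.9, .8, .4), c = .5 -> (0.1+0.2)/2."""
        pi = np.array([[0.9, 0.8, 0.4]])
        assert bayes_fdr(pi, 0.5) == pytest.approx(0.15)
        assert bayes_fdr(pi, 0.85) == pytest.approx(0.1)
        assert bayes_fdr(pi, 0.95) == 0.0  # empty set convention

    @given(st.integers(0, 500))
    def test_non_increasing_in_threshold(self, seed):
        pi = np.random.default_rng(seed).random(30)
        cs = np.linspace(0.0, 0.99, 25)
        vals = [bayes_fdr(pi, c) for c in cs if np.any(pi > c)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_threshold_contract(self):
        pi = np.array([0.99, 0.97, 0.6, 0.2])
        thr = threshold_for_bfdr(pi, 0.05)
        assert thr is not NO_CALLS
        assert bayes_fdr(pi, thr) <= 0.05
        # it is the smallest candidate attaining the target
        smaller = [c for c in np.append(np.unique(pi), 0.0) if c < thr and np.any(pi > c)]
        assert all(bayes_fdr(pi, c) > 0.05 for c in smaller)

    def test_no_calls_sentinel(self):
        pi = np.array([0.5, 0.4, 0.3])
        assert threshold_for_bfdr(pi, 0.01) is NO_CALLS

    def test_zero_threshold_allowed(self):
        pi = np.array([0.99, 0.999])
        assert threshold_for_bfdr(pi, 0.05) == 0.0  # everything is callable

    @given(st.integers(0, 200))
    def test_threshold_achieves_target_when_found(self, seed):
        pi = np.random.default_rng(seed).random(25)
        thr = threshold_for_bfdr(pi, 0.2)
        if thr is not NO_CALLS:
            assert bayes_fdr(pi, thr) <= 0.2
            assert np.any(pi > thr)


class TestCallsAndHotspots:
    def test_mppi_and_calls(self):
        tr = make_trace([[3, 0], [2, 1]], 4)
        mppi = compute_mppi(tr)
        assert np.allclose(mppi, [[0.75, 0.0], [0.5, 0.25]])
        calls = association_calls(mppi, 0.4, ["a", "b"], ["m1", "m2"])
        assert calls["called"].tolist() == [True, False, True, False]

    def test_hotspot_table_sorted(self):
        mppi = np.array([[0.9, 0.1, 0.95], [0.8, 0.2, 0.1], [0.99, 0.0, 0.97]])
        calls = association_calls(mppi, 0.5)
        tab = hotspot_table(calls)
        assert tab.iloc[0]["marker_id"] == "m0" and tab.iloc[0]["n_responses"] == 3
        assert tab["n_responses"].tolist() == [3, 2, 0]

    def test_hotspot_table_no_calls(self):
        calls = association_calls(np.array([[0.1, 0.2]]), 0.9)
        tab = hotspot_table(calls)
        assert tab["n_responses"].tolist() == [0, 0]


class TestModelSummaries:
    def _engine(self):
        X, stacks = make_small_fixture(3, n=8, p=4, q=1, r=2, signal=1.0)
        hp = HyperParams(h=np.array([0.25]))
        return X, stacks, hp, MarginalLikelihoodEngine(X, stacks, hp)

    def test_best_model_is_argmax(self):
        X, stacks, hp, eng = self._engine()
        visited = [{(): 5, (0,): 50, (0, 1): 10, (2,): 3}]
        tr = make_trace(np.zeros((1, 4)), 68, visited=visited, g=[5.0],
                        omega=[[0.3]], rho=[[1.0] * 4])
        bm = best_model(tr, 0, eng, hp)
        probs = renormalized_model_probs(tr, 0, eng, hp)
        assert bm == max(probs, key=probs.get)
        assert pytest.approx(sum(probs.values())) == 1.0

    def test_best_model_tie_break(self):
        """Exact ties resolve toward the smaller model, then lexicographically."""
        X, stacks, hp, eng = self._engine()

        class TiedEngine:
            p = 4

            def log_marginal_nocache(self, k, row, g):
                return 0.0

        visited = [{(1, 2): 4, (0,): 4, (2,): 4}]
        tr = make_trace(np.zeros((1, 4)), 12, visited=visited, g=[5.0],
                        omega=[[0.5]], rho=[[1.0] * 4])
        # with a flat likelihood and omega = 0.5, rho = 1 all rows of equal size tie
        bm = best_model(tr, 0, TiedEngine(), hp)
        assert bm == (0,)

    def test_empty_visited_raises(self):
        X, stacks, hp, eng = self._engine()
        tr = make_trace(np.zeros((1, 4)), 1, visited=[dict()])
        with pytest.raises(ValueError):
            best_model(tr, 0, eng, hp)


class TestAdequacy:
    def test_true_model_beats_missing_predictor(self):
        """direction check on one seeded dataset."""
        rng = np.random.default_rng(12)
        n, p, r = 25, 6, 2
        X = (rng.random((n, p)) < 0.5).astype(float)
        Y = 0.8 * X[:, [1]] + 0.5 * X[:, [4]] + 0.25 * rng.standard_normal((n, r))
        hp = HyperParams(h=np.array([0.0625]))
        tr = make_trace(np.zeros((1, p)), 10, g=np.full(50, 10.0))
        s_true, e_true = loo_checking_function(X, Y, (1, 4), tr, hp, 0, np.random.default_rng(0))
        s_miss, _ = loo_checking_function(X, Y, (4,), tr, hp, 0, np.random.default_rng(0))
        assert e_true.shape == (n, r)
        assert np.all(np.isfinite(e_true))
        assert s_true < s_miss

    def test_adequacy_score_near_expected_under_truth(self):
        """Sum of squared standardized errors should be near n*r under adequacy."""
        rng = np.random.default_rng(21)
        n, p, r = 30, 4, 2
        X = (rng.random((n, p)) < 0.5).astype(float)
        Y = 0.7 * X[:, [0]] + 0.3 * rng.standard_normal((n, r))
        hp = HyperParams(h=np.array([0.09]))
        tr = make_trace(np.zeros((1, p)), 10, g=np.full(50, 8.0))
        s, _ = loo_checking_function(X, Y, (0,), tr, hp, 0, np.random.default_rng(1))
        assert 0.5 * n * r < s < 2.0 * n * r
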