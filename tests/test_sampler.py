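"""Sampler correctness against exact enumeration and numerical quadrature."""

import numpy as np
import pytest
from scipy import integrate

from mthess.likelihood import HyperParams, MarginalLikelihoodEngine
from mthess.priors import log_prior_g
from mthess.sampler import (
    LadderConfig,
    SamplerConfig,
    exact_enumeration,
    run_sampler,
    tune_ladder,
)

from conftest import make_small_fixture


def test_fixed_parameter_mppi_matches_enumeration():
    """with (omega, rho, g) fixed the sampler targets a fully enumerable posterior."""
    X, stacks = make_small_fixture(5, n=8, p=5, q=2, r=2, signal=0.8)
    hp = HyperParams(h=np.array([0.2, 0.2]))
    cfg = SamplerConfig(n_sweeps=20_000, burn_in=2_000, seed=0, update_omega=False,
                        update_rho=False, update_g=False, log_every=0)
    tr = run_sampler(X, stacks, hp, cfg, omega0=0.3, rho0=1.0, g0=5.0)
    mppi = tr.gamma_inclusion_counts / tr.n_recorded
    exact = exact_enumeration(X, stacks, hp, 0.3, 1.0, 5.0)
    assert np.abs(mppi - exact).max() < 0.03


def test_g_posterior_matches_quadrature():
    """posterior mean of g agrees with 1-D quadrature (p = 1 toy)."""
    rng = np.random.default_rng(9)
    n = 10
    X = np.array([0.0, 1, 0, 1, 1, 0, 1, 0, 1, 0])[:, None]
    y = (0.9 * X[:, 0] + 0.3 * rng.standard_normal(n))[:, None]
    hp = HyperParams(h=np.array([0.1]), a_g=0.5, b_g=n / 2.0)
    omega = 0.4
    eng = MarginalLikelihoodEngine(X, y[None, :, :], hp)

    def joint(g, row):
        pri = np.log(omega) if row else np.log1p(-omega)
        return np.exp(eng.log_marginal(0, row, g) + pri + log_prior_g(g, hp.a_g, hp.b_g))

    # the posterior of g is heavy tailed (infinite variance), so compare the
    # posterior mean of log g, which is a stable functional
    num = sum(integrate.quad(lambda g, r=row: np.log(g) * joint(g, r), 1e-8, 5000, limit=400)[0]
              for row in [(), (0,)])
    den = sum(integrate.quad(lambda g, r=row: joint(g, r), 1e-8, 5000, limit=400)[0]
              for row in [(), (0,)])
    e_logg_exact = num / den
    p_inc_exact = (
        integrate.quad(lambda g: joint(g, (0,)), 1e-8, 5000, limit=400)[0] / den
    )

    cfg = SamplerConfig(n_sweeps=40_000, burn_in=5_000, seed=1, update_omega=False,
                        update_rho=False, log_every=0)
    tr = run_sampler(X, y[None, :, :], hp, cfg, omega0=omega, rho0=1.0)
    assert np.mean(np.log(tr.g_samples)) == pytest.approx(e_logg_exact, abs=0.15)
    p_inc = tr.gamma_inclusion_counts[0, 0] / tr.n_recorded
    assert p_inc == pytest.approx(p_inc_exact, abs=0.02)


def test_block_exchange_alone_matches_enumeration():
    """the per-response block swap preserves the fixed-parameter target."""
    X, stacks = make_small_fixture(11, n=8, p=4, q=2, r=2, signal=0.7)
    hp = HyperParams(h=np.array([0.25, 0.25]))
    cfg = SamplerConfig(n_sweeps=20_000, burn_in=2_000, seed=4, update_omega=False,
                        update_rho=False, update_g=False, crossover=False,
                        exchange=False, block_exchange=True, log_every=0)
    tr = run_sampler(X, stacks, hp, cfg, omega0=0.3, rho0=1.0, g0=5.0)
    mppi = tr.gamma_inclusion_counts / tr.n_recorded
    exact = exact_enumeration(X, stacks, hp, 0.3, 1.0, 5.0)
    assert np.abs(mppi - exact).max() < 0.03
    acc, tot = tr.acceptance_stats["block_exchange"]
    assert tot > 0 and 0 < acc <= tot


def test_determinism_same_seed():
    X, stacks = make_small_fixture(2, n=7, p=4, q=2, r=2)
    hp = HyperParams(h=np.array([0.3, 0.3]), a_omega=np.array([1.0, 1.0]),
                     b_omega=np.array([9.0, 9.0]))
    cfg = SamplerConfig(n_sweeps=2_000, burn_in=500, seed=42, log_every=0)
    t1 = run_sampler(X, stacks, hp, cfg)
    t2 = run_sampler(X, stacks, hp, cfg)
    assert np.array_equal(t1.gamma_inclusion_counts, t2.gamma_inclusion_counts)
    assert np.array_equal(t1.g_samples, t2.g_samples)
    assert np.array_equal(t1.omega_samples, t2.omega_samples)


def test_different_seed_differs():
    X, stacks = make_small_fixture(2, n=7, p=4, q=2, r=2)
    hp = HyperParams(h=np.array([0.3, 0.3]), a_omega=np.array([1.0, 1.0]),
                     b_omega=np.array([9.0, 9.0]))
    t1 = run_sampler(X, stacks, hp, SamplerConfig(n_sweeps=2_000, burn_in=500, seed=1, log_every=0))
    t2 = run_sampler(X, stacks, hp, SamplerConfig(n_sweeps=2_000, burn_in=500, seed=2, log_every=0))
    assert not np.array_equal(t1.g_samples, t2.g_samples)


def test_internal_consistency_debug_checks():
    """debug mode revalidates every cached likelihood and the prior constraint."""
    X, stacks = make_small_fixture(7, n=8, p=5, q=2, r=2, signal=0.5)
    hp = HyperParams(h=np.array([0.3, 0.3]), a_omega=np.array([1.0, 1.0]),
                     b_omega=np.array([4.0, 4.0]))
    cfg = SamplerConfig(n_sweeps=1_500, burn_in=300, seed=3, debug_checks=True, log_every=0)
    tr = run_sampler(X, stacks, hp, cfg)  # raises AssertionError on inconsistency
    assert tr.n_recorded == 1_200


def test_trace_bookkeeping():
    X, stacks = make_small_fixture(0, n=7, p=4, q=2, r=2)
    hp = HyperParams(h=np.array([0.3, 0.3]), a_omega=np.array([1.0, 1.0]),
                     b_omega=np.array([5.0, 5.0]))
    cfg = SamplerConfig(n_sweeps=1_000, burn_in=400, seed=0, log_every=0)
    tr = run_sampler(X, stacks, hp, cfg)
    assert tr.n_recorded == 600
    assert tr.g_samples.shape == (600,)
    assert (tr.gamma_inclusion_counts >= 0).all()
    assert (tr.gamma_inclusion_counts <= 600).all()
    for k in range(2):
        assert sum(tr.visited_models[k].values()) == 600
    assert np.all(np.diff(tr.temperatures) > 0) and tr.temperatures[0] == 1.0


def test_tune_ladder_direction():
    lad = LadderConfig(target_swap_rate=0.5)
    assert tune_ladder(0.9, lad, 2.0) > 2.0  # too many swaps -> spread out
    assert tune_ladder(0.1, lad, 2.0) < 2.0  # too few -> pull together
    assert tune_ladder(0.0, lad, 1.0) >= 1.01


def test_config_validation():
    with pytest.raises(ValueError):
        SamplerConfig(n_sweeps=10, burn_in=10).validate()
    with pytest.raises(ValueError):
        SamplerConfig(move_probabilities={"add": 0.5, "delete": 0.5, "swap": 0.5}).validate()
    with pytest.raises(ValueError):
        SamplerConfig(response_update_fraction=0.0).validate()


def test_size_cap_respected():
    X, stacks = make_small_fixture(1, n=6, p=5, q=1, r=1)
    hp = HyperParams(h=np.array([0.5]), max_model_size=2,
                     a_omega=np.array([3.0]), b_omega=np.array([3.0]))
    cfg = SamplerConfig(n_sweeps=3_000, burn_in=500, seed=0, record_full_gamma=True, log_every=0)
    tr = run_sampler(X, stacks, hp, cfg)
    for rows in tr.gamma_samples:
        assert all(len(r) <= 2 for r in rows)


def test_enumeration_guard():
    X, stacks = make_small_fixture(0, n=6, p=4, q=1, r=1)
    hp = HyperParams(h=np.array([0.5]))
    with pytest.raises(ValueError):
        exact_enumeration(np.ones((6, 13)), stacks, hp, 0.2, 1.0, 1.0)
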