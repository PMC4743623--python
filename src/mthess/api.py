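"""High-level fitting interface: elicit hyperparameters, run the sampler, summarize."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import GenotypePanel, ResponsePanel
from .likelihood import HyperParams, MarginalLikelihoodEngine
from .postprocess import compute_mppi
from .priors import PriorSpec, elicit_omega_hyperparams, empirical_h, g_prior_params
from .sampler import LadderConfig, PosteriorTrace, SamplerConfig, run_sampler

logger = logging.getLogger(__name__)

__all__ = ["FitResult", "fit_mthess"]


@dataclass
class FitResult:
    trace: PosteriorTrace
    mppi: np.ndarray
    hp: HyperParams
    engine: MarginalLikelihoodEngine
    config: SamplerConfig


def fit_mthess(
    X: GenotypePanel | np.ndarray,
    Y: ResponsePanel | np.ndarray,
    *,
    e_gamma: float | np.ndarray = 2.0,
    v_gamma: float | np.ndarray = 8.0,
    n_sweeps: int = 15_000,
    burn_in: int = 5_000,
    n_chains: int = 3,
    seed: int = 0,
    h_mode: str = "empirical",
    h_value: float | None = None,
    d: float = 3.0,
    c_rho: float = 1.2,
    d_rho: float = 1.2,
    max_model_size: int = 15,
    sampler_overrides: dict | None = None,
) -> FitResult:
    """Fit the multi-condition hierarchical sparse-regression model.

    Elicits the Beta sparsity parameters from the target prior mean and
    variance of the model size, the inverse-gamma shrinkage prior from (n, q),
    and the error-variance scales h_k by stepwise regression per condition
    (``h_mode='empirical'``) or a fixed value (``h_mode='fixed'``).
    """
    Xv = X.values if isinstance(X, GenotypePanel) else np.asarray(X, dtype=float)
    if isinstance(Y, ResponsePanel):
        stacks = Y.stacks
    else:
        stacks = np.asarray(Y, dtype=float)
        if stacks.ndim == 2:
            stacks = stacks[None]
    q, n, r = stacks.shape
    p = Xv.shape[1]
    spec = PriorSpec(e_gamma=e_gamma, v_gamma=v_gamma, n=n, q=q, p=p)
    a_om, b_om = elicit_omega_hyperparams(spec)
    a_g, b_g = g_prior_params(n, q)
    if h_mode == "empirical":
        if isinstance(X, GenotypePanel) and isinstance(Y, ResponsePanel):
            Xp, Yp = X, Y
        else:
            Xp = GenotypePanel(Xv, [f"s{i}" for i in range(n)], [f"m{j}" for j in range(p)])
            Yp = ResponsePanel(stacks, [f"y{k}" for k in range(q)],
                               [f"c{j}" for j in range(r)], Xp.sample_ids)
        h = np.array([empirical_h(Yp, Xp, k) for k in range(q)])
    elif h_mode == "fixed":
        if h_value is None or h_value <= 0:
            raise ValueError("h_mode='fixed' requires a positive h_value")
        h = np.full(q, float(h_value))
    else:
        raise ValueError("h_mode must be 'empirical' or 'fixed'")
    hp = HyperParams(d=d, h=h, a_g=a_g, b_g=b_g, a_omega=a_om, b_omega=b_om,
                     c_rho=c_rho, d_rho=d_rho, max_model_size=max_model_size)
    cfg = SamplerConfig(n_sweeps=n_sweeps, burn_in=burn_in, seed=seed,
                        **(sampler_overrides or {}))
    ladder = LadderConfig(n_chains=n_chains)
    engine = MarginalLikelihoodEngine(Xv, stacks, hp)
    logger.info("fitting: n=%d p=%d q=%d r=%d sweeps=%d chains=%d", n, p, q, r, n_sweeps, n_chains)
    trace = run_sampler(Xv, stacks, hp, cfg, ladder, engine=engine)
    return FitResult(trace=trace, mppi=compute_mppi(trace), hp=hp, engine=engine, config=cfg)
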