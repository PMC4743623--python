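"""Posterior summaries: association calls, Bayesian FDR, hotspots, model adequacy.

The per-pair evidence is the marginal posterior probability of inclusion
(MPPI) ``pi_kj = P(gamma_kj = 1 | data)``, estimated by the fraction of
recorded sweeps with the pair included.  Calls are made by thresholding the
MPPI, either directly or by choosing the smallest threshold whose Bayesian
FDR

    bFDR(c) = sum_(kj) (1 - pi_kj) 1[pi_kj > c] / sum_(kj) 1[pi_kj > c]

stays below a target.  Hotspots are markers called for many responses.  Model
adequacy is a leave-one-out posterior-predictive check: each held-out
observation is compared with its predictive distribution under the best model
visited, and the squared standardized prediction errors are summed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import multigammaln
from scipy.stats import invwishart

from .likelihood import HyperParams, center_columns
from .priors import log_prior_gamma_row
from .sampler import PosteriorTrace

logger = logging.getLogger(__name__)

__all__ = [
    "compute_mppi",
    "bayes_fdr",
    "threshold_for_bfdr",
    "association_calls",
    "hotspot_table",
    "best_model",
    "renormalized_model_probs",
    "loo_checking_function",
    "AdequacyReport",
    "NO_CALLS",
]

NO_CALLS = None  # sentinel returned by threshold_for_bfdr when no threshold attains the target


def compute_mppi(trace: PosteriorTrace) -> np.ndarray:
    """MPPI matrix: inclusion counts divided by recorded sweeps."""
    if trace.n_recorded < 1:
        raise ValueError("trace has no recorded sweeps")
    return trace.gamma_inclusion_counts / trace.n_recorded


def bayes_fdr(mppi, c: float) -> float:
    """Bayesian FDR of the call set {pi > c}; 0 by convention when empty."""
    if not 0 <= c < 1:
        raise ValueError("threshold must lie in [0, 1)")
    pi = np.asarray(mppi, dtype=float).ravel()
    called = pi > c
    if not called.any():
        logger.warning("bFDR: no MPPI exceeds threshold %.3f; returning 0 by convention", c)
        return 0.0
    return float(np.sum(1.0 - pi[called]) / called.sum())


def threshold_for_bfdr(mppi, target: float):
    """Smallest observed-MPPI threshold c with bFDR(c) <= target.

    Candidate thresholds are the observed MPPI values (calling everything
    strictly above each).  Returns ``NO_CALLS`` if no candidate attains the
    target with a non-empty call set.
    """
    if not 0 < target < 1:
        raise ValueError("target must lie in (0, 1)")
    pi = np.asarray(mppi, dtype=float).ravel()
    # candidate thresholds: observed values plus 0 (call everything above zero);
    # bFDR is non-increasing in c, so scan descending and keep the last success
    order = np.sort(np.unique(np.append(pi, 0.0)))
    best = NO_CALLS
    for c in order[::-1]:
        if c >= 1.0 or not np.any(pi > c):
            continue
        if bayes_fdr(pi, float(c)) <= target:
            best = float(c)
        else:
            break
    return best


def association_calls(
    mppi: np.ndarray,
    threshold: float,
    response_ids=None,
    marker_ids=None,
) -> pd.DataFrame:
    """Long-format table of all pairs with their MPPI and call flag at a threshold."""
    q, p = mppi.shape
    response_ids = response_ids if response_ids is not None else [f"y{k}" for k in range(q)]
    marker_ids = marker_ids if marker_ids is not None else [f"m{j}" for j in range(p)]
    kk, jj = np.meshgrid(np.arange(q), np.arange(p), indexing="ij")
    return pd.DataFrame(
        {
            "response_id": np.asarray(response_ids)[kk.ravel()],
            "marker_id": np.asarray(marker_ids)[jj.ravel()],
            "mppi": mppi.ravel(),
            "called": mppi.ravel() > threshold,
            "threshold_used": threshold,
        }
    )


def hotspot_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-marker counts of called responses, sorted descending (ties by marker order)."""
    order = calls["marker_id"].drop_duplicates().tolist()
    counts = (
        calls[calls["called"]].groupby("marker_id", sort=False)["response_id"].count()
        if calls["called"].any()
        else pd.Series(dtype=int)
    )
    tab = pd.DataFrame({"marker_id": order})
    tab["n_responses"] = tab["marker_id"].map(counts).fillna(0).astype(int)
    tab["_ord"] = np.arange(len(tab))
    tab = tab.sort_values(["n_responses", "_ord"], ascending=[False, True]).drop(columns="_ord")
    return tab.reset_index(drop=True)


def _model_score(engine, hp: HyperParams, k: int, row: tuple, omega_k: float, rho: np.ndarray, g: float) -> float:
    p = engine.p
    mask = np.zeros(p, dtype=bool)
    if row:
        mask[list(row)] = True
    return engine.log_marginal_nocache(k, row, g) + log_prior_gamma_row(mask, min(omega_k, 1.0 / max(rho.max(), 1e-12)), rho)


def best_model(trace: PosteriorTrace, k: int, engine, hp: HyperParams) -> tuple:
    """Best model visited for response k: maximal log posterior score.

    Scored as marginal likelihood plus the row prior evaluated at the
    posterior means of (omega, rho, g).  Ties break toward the smaller model,
    then lexicographically.
    """
    visited = trace.visited_models[k]
    if not visited:
        raise ValueError(f"no visited models recorded for response {k}")
    om, rho, g = float(trace.omega_mean[k]), trace.rho_mean, trace.g_mean
    scored = [(-_model_score(engine, hp, k, row, om, rho, g), len(row), row) for row in visited]
    scored.sort()
    return scored[0][2]


def renormalized_model_probs(trace: PosteriorTrace, k: int, engine, hp: HyperParams) -> dict:
    """Posterior model probabilities renormalized over the visited set."""
    visited = trace.visited_models[k]
    if not visited:
        raise ValueError(f"no visited models recorded for response {k}")
    om, rho, g = float(trace.omega_mean[k]), trace.rho_mean, trace.g_mean
    rows = list(visited)
    scores = np.array([_model_score(engine, hp, k, row, om, rho, g) for row in rows])
    w = np.exp(scores - scores.max())
    w /= w.sum()
    return dict(zip(rows, w))


@dataclass
class AdequacyReport:
    """Leave-one-out adequacy: per-observation standardized errors and their square sums."""

    per_response: np.ndarray  # (q,) sums of squared standardized errors
    per_observation: list  # q arrays of shape (n, r)


def _log_marginal_small(Yc: np.ndarray, Xg: np.ndarray, g: float, h: float, d: float) -> float:
    """Marginal log likelihood of a centered data block (for the LOO g grid weights)."""
    m, r = Yc.shape  # m rows retained, centered: m - 1 effective
    nu = d + r - 1.0
    YtY = Yc.T @ Yc
    S = h * np.eye(r) + YtY
    mm = 0
    if Xg.shape[1] > 0:
        K = Xg.T @ Xg
        cf = cho_factor(K, lower=True)
        B = Xg.T @ Yc
        S = S - (g / (1.0 + g)) * (B.T @ cho_solve(cf, B))
        mm = Xg.shape[1]
    _, ld = np.linalg.slogdet(S)
    return float(-0.5 * r * mm * np.log1p(g) - 0.5 * (nu + m - 1.0) * ld + multigammaln(0.5 * (nu + m - 1.0), r))


def loo_checking_function(
    X: np.ndarray,
    Y_k: np.ndarray,
    best: tuple,
    trace: PosteriorTrace,
    hp: HyperParams,
    k: int = 0,
    rng: np.random.Generator | None = None,
    n_draws: int = 200,
    grid_size: int = 21,
) -> tuple[float, np.ndarray]:
    """Leave-one-out standardized prediction errors under the best model.

    For each held-out observation i, draws from the posterior predictive of
    ``y_ik`` given the remaining data and the best model: g is integrated
    numerically on a log grid spanning its sampled range, and (Sigma, B, A)
    are drawn from their conjugate conditional posteriors.  The checking
    function is (observed - predictive mean) / predictive SD per condition;
    the adequacy score is the sum of squares over observations and conditions.
    """
    rng = rng or np.random.default_rng(0)
    X = np.asarray(X, dtype=float)
    Y_k = np.asarray(Y_k, dtype=float)
    n, r = Y_k.shape
    idx = np.asarray(best, dtype=int)
    m = idx.size
    if n < m + 3:
        raise ValueError("too few observations for leave-one-out with this model size")
    hk = float(hp.h[k] if hp.h.size > 1 else hp.h[0])
    nu = hp.d + r - 1.0
    gs = np.asarray(trace.g_samples, dtype=float)
    glo, ghi = np.quantile(gs, 0.005), np.quantile(gs, 0.995)
    if ghi <= glo:
        ghi = glo * 1.0001 + 1e-6
    grid = np.exp(np.linspace(np.log(glo), np.log(ghi), grid_size))
    errors = np.empty((n, r))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Yi = Y_k[keep]
        Xi = X[keep][:, idx]
        ybar = Yi.mean(axis=0)
        xbar = Xi.mean(axis=0)
        Yc = Yi - ybar
        Xc = Xi - xbar
        mrows = n - 1
        # posterior weights of g on the grid (prior x marginal likelihood)
        logw = np.array(
            [
                _log_marginal_small(Yc, Xc, g, hk, hp.d)
                + (-(hp.a_g + 1.0) * np.log(g) - hp.b_g / g)
                for g in grid
            ]
        )
        w = np.exp(logw - logw.max())
        w /= w.sum()
        counts = rng.multinomial(n_draws, w)
        if m > 0:
            K = Xc.T @ Xc
            cf = cho_factor(K, lower=True)
            Kinv = cho_solve(cf, np.eye(m))
            Lk = np.linalg.cholesky(Kinv + 1e-12 * np.eye(m))
            XtY = Xc.T @ Yc
            YtY = Yc.T @ Yc
            R = YtY - XtY.T @ cho_solve(cf, XtY)
        else:
            YtY = Yc.T @ Yc
        draws = np.empty((n_draws, r))
        pos = 0
        for g, c in zip(grid, counts):
            if c == 0:
                continue
            shrink = g / (1.0 + g)
            S0 = (YtY - shrink * (XtY.T @ cho_solve(cf, XtY))) if m > 0 else YtY
            Sig = invwishart.rvs(df=nu + mrows - 1.0, scale=hk * np.eye(r) + S0, size=c, random_state=rng)
            Sig = np.asarray(Sig).reshape(c, r, r)
            Ls = np.linalg.cholesky(Sig)
            if m > 0:
                MB = shrink * cho_solve(cf, XtY)  # (m, r) posterior mean of B
                Gz = rng.standard_normal((c, m, r))
                B = MB[None] + np.sqrt(shrink) * np.einsum("ij,cjl,cml->cim", Lk, Gz, Ls)
                xb = np.einsum("j,cjl->cl", X[i, idx] - xbar, B)
            else:
                xb = np.zeros((c, r))
            A = ybar[None] + np.einsum("cl,clm->cm", rng.standard_normal((c, r)), Ls) / np.sqrt(mrows)
            eps = np.einsum("cl,clm->cm", rng.standard_normal((c, r)), Ls)
            draws[pos : pos + c] = A + xb + eps
            pos += c
        mu = draws.mean(axis=0)
        sd = draws.std(axis=0, ddof=1)
        errors[i] = (Y_k[i] - mu) / sd
    return float(np.sum(errors**2)), errors
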