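"""Prior densities and hyperparameter elicitation for the hierarchical selection model.

The inclusion probability of marker ``j`` in response ``k`` decomposes as
``omega_kj = omega_k * rho_j``: a per-response sparsity level ``omega_k ~
Beta(a_k, b_k)`` and a per-marker hotspot propensity ``rho_j ~
Gamma(c, rate d)`` centred on 1, constrained so that ``omega_k * rho_j <= 1``.
The Beta parameters are elicited by back-calculation from a target prior mean
and variance of the model size |gamma_k|, treating rho as 1 a priori so the
size is beta-binomial.  The global shrinkage factor g carries an inverse-gamma
prior; for a single response this is the Zellner–Siow choice InvGamma(1/2, n/2)
and for q responses the shape grows with q while the prior mode stays n/3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import GenotypePanel, ResponsePanel

__all__ = [
    "PriorSpec",
    "ElicitationError",
    "elicit_omega_hyperparams",
    "g_prior_params",
    "log_prior_gamma_row",
    "log_prior_omega",
    "log_prior_rho",
    "log_prior_g",
    "empirical_h",
    "forward_stepwise_variance",
]


class ElicitationError(ValueError):
    pass


@dataclass
class PriorSpec:
    """Targets for prior elicitation: E(|gamma_k|) and Var(|gamma_k|) per response."""

    e_gamma: np.ndarray
    v_gamma: np.ndarray
    n: int
    q: int
    p: int

    def __post_init__(self) -> None:
        self.e_gamma = np.broadcast_to(np.atleast_1d(np.asarray(self.e_gamma, float)), (self.q,)).copy()
        self.v_gamma = np.broadcast_to(np.atleast_1d(np.asarray(self.v_gamma, float)), (self.q,)).copy()
        if np.any(self.e_gamma <= 0) or np.any(self.e_gamma >= self.p):
            raise ElicitationError("E(|gamma_k|) must lie in (0, p)")
        binom_var = self.e_gamma * (1.0 - self.e_gamma / self.p)
        if np.any(self.v_gamma <= binom_var):
            raise ElicitationError(
                "Var(|gamma_k|) must exceed the binomial variance E(1 - E/p); "
                f"violated bound: Var > {binom_var.max():.6g}"
            )


def elicit_omega_hyperparams(spec: PriorSpec) -> tuple[np.ndarray, np.ndarray]:
    """Back-calculate per-response Beta(a, b) parameters from (E, Var) of |gamma_k|.

    Solves the beta-binomial moment equations
    ``E = p mu`` and ``Var = p mu (1-mu) [1 + (p-1)/(a+b+1)]`` with
    ``mu = a/(a+b)``, treating rho_j as 1 (its prior centre).
    """
    p = spec.p
    mu = spec.e_gamma / p
    phi = spec.v_gamma / (p * mu * (1.0 - mu))  # overdispersion factor, must be in (1, p)
    if np.any(phi >= p):
        raise ElicitationError("Var(|gamma_k|) too large: implied a+b would be non-positive")
    s = (p - 1.0) / (phi - 1.0) - 1.0  # a + b
    if np.any(s <= 0):
        raise ElicitationError("no proper Beta solution: variance target too extreme")
    return mu * s, (1.0 - mu) * s


def g_prior_params(n: int, q: int) -> tuple[float, float]:
    """Inverse-gamma parameters for g: (q/2 + q - 1, n q / 2).

    Reduces to Zellner–Siow InvGamma(1/2, n/2) at q = 1; the implied mode
    b/(a+1) = n/3 is constant in q while the prior precision grows with q.
    """
    if n < 1 or q < 1:
        raise ValueError("n and q must be positive")
    return q / 2.0 + q - 1.0, n * q / 2.0


def log_prior_gamma_row(gamma, omega_k: float, rho: np.ndarray) -> float:
    """Log prior of one inclusion row: independent Bernoulli(omega_k * rho_j)."""
    gamma = np.asarray(gamma)
    if gamma.dtype != bool:
        gamma = gamma.astype(bool)
    w = omega_k * np.asarray(rho, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("omega_k * rho_j outside [0, 1]: sampler constraint violated")
    with np.errstate(divide="ignore"):
        lp = np.where(gamma, np.log(w), np.log1p(-w))
    return float(np.sum(lp))


def log_prior_omega(omega_k: float, a_omega_k: float, b_omega_k: float) -> float:
    if not 0.0 < omega_k < 1.0:
        raise ValueError("omega_k outside (0, 1)")
    return float(stats.beta.logpdf(omega_k, a_omega_k, b_omega_k))


def log_prior_rho(rho_j: float, c_rho: float, d_rho: float) -> float:
    """Gamma(shape c, rate d) log density; c = d centres rho on mean 1."""
    if rho_j <= 0:
        raise ValueError("rho_j must be strictly positive")
    return float(stats.gamma.logpdf(rho_j, c_rho, scale=1.0 / d_rho))


def log_prior_g(g: float, a_g: float, b_g: float) -> float:
    """Inverse-gamma log density, p(g) ∝ g^{-a-1} exp(-b/g); mode b/(a+1)."""
    if g <= 0:
        raise ValueError("g must be strictly positive")
    # direct formula: scipy's frozen-distribution dispatch is ~100x slower
    # and this sits on the sampler's per-sweep path
    return a_g * math.log(b_g) - math.lgamma(a_g) - (a_g + 1.0) * math.log(g) - b_g / g


def forward_stepwise_variance(
    y: np.ndarray,
    X: np.ndarray,
    alpha: float | None = None,
    max_terms: int = 5,
) -> float:
    """Residual variance after forward-stepwise selection on one response column.

    Predictors enter while the best partial F-test has p-value < ``alpha``, up
    to ``max_terms`` terms.  Because the best of p candidates is tested at
    each step, the default entry level is Bonferroni-adjusted (0.05 / p);
    an unadjusted level badly deflates the variance estimate when p >> n.
    The returned variance uses the unbiased denominator n - (selected + 1).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if alpha is None:
        alpha = 0.05 / p
    if np.std(y) == 0:
        raise ValueError("zero-variance response column")
    resid = y - y.mean()
    # orthonormal basis of selected columns (plus intercept, handled by centering)
    Xw = X - X.mean(axis=0, keepdims=True)
    Q = np.empty((n, 0))
    n_sel = 0
    rss = float(resid @ resid)
    while n_sel < min(max_terms, p, n - 3):
        Xp = Xw - Q @ (Q.T @ Xw) if Q.shape[1] else Xw
        norms = np.einsum("ij,ij->j", Xp, Xp)
        ok = norms > 1e-10 * max(1.0, float(norms.max(initial=1.0)))
        if not ok.any():
            break
        proj = np.zeros(p)
        proj[ok] = (Xp[:, ok].T @ resid) ** 2 / norms[ok]
        j = int(np.argmax(proj))
        rss_new = rss - proj[j]
        df_resid = n - n_sel - 2  # intercept + selected + candidate
        if df_resid <= 0 or rss_new <= 0:
            break
        f = (rss - rss_new) / (rss_new / df_resid)
        if stats.f.sf(f, 1, df_resid) >= alpha:
            break
        qv = Xp[:, j] / np.sqrt(norms[j])
        Q = np.column_stack([Q, qv])
        resid = resid - qv * (qv @ resid)
        rss = float(resid @ resid)
        n_sel += 1
    return rss / (n - n_sel - 1)


def empirical_h(Y: ResponsePanel, X: GenotypePanel, k: int, alpha: float | None = None, max_terms: int = 5) -> float:
    """Empirical-Bayes error-variance scale h_k.

    Runs a forward-stepwise regression of response k on the markers separately
    in each condition and returns the median of the condition-specific residual
    variance estimates.
    """
    stack = Y.stacks[k]  # (n, r)
    ests = [forward_stepwise_variance(stack[:, ell], X.values, alpha, max_terms) for ell in range(Y.r)]
    return float(np.median(ests))
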