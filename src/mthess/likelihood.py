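"""Matrix-variate data model and the conditional marginal likelihood.

Each response ``k`` is an ``n x r`` matrix ``Y_k`` (individuals by conditions)
modelled as ``Y_k = A_k + X_gamma B_gamma + E_k`` with matrix-normal noise
``E_k ~ N(I_n, Sigma_k)``: rows (individuals) independent, columns (conditions)
correlated through the ``r x r`` covariance ``Sigma_k``.  Conjugate priors — a
flat prior on the intercept ``A_k``, a g-prior ``B_gamma | Sigma_k, g ~
N(0, g (X_g' X_g)^{-1}, Sigma_k)`` and an inverse-Wishart on ``Sigma_k`` —
let ``A_k``, ``B_gamma`` and ``Sigma_k`` be integrated analytically, giving

    p(Y_k | X, gamma_k, g) ∝ (1+g)^{-r|gamma_k|/2}
        x | h_k I_r + (1/(1+g)) Yc'Yc + (g/(1+g)) R(gamma_k) |^{-(d+n+r-2)/2}

with ``Yc`` the column-centered response, ``R(gamma) = Yc'Yc -
Yc'X_g (X_g'X_g)^{-1} X_g'Yc`` the residual cross-product, and ``d`` the
inverse-Wishart shape (E(Sigma_k) = h_k I_r at d = 3).  The flat intercept is
integrated by centering, which leaves n-1 effective observations; together
with the Wishart shape (d + r - 1 in the standard convention) this produces
the ``(d + n + r - 2)/2`` exponent.  :func:`log_marginal` returns the exact
log density including all constants, so it can be validated directly against
:func:`oracle_log_marginal_mc`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotrf, dtrtrs
from scipy.special import multigammaln
from scipy.stats import invwishart

from .data import GenotypePanel, ResponsePanel, dedupe_markers  # noqa: F401  (re-export)

__all__ = [
    "HyperParams",
    "ModelIndicatorRow",
    "SingularDesignError",
    "center_columns",
    "residual_quadratic",
    "log_marginal",
    "oracle_log_marginal_mc",
    "MarginalLikelihoodEngine",
    "dedupe_markers",
]


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the selected design columns are (numerically) rank deficient."""


@dataclass
class ModelIndicatorRow:
    """Binary inclusion vector ``gamma_k`` for one response."""

    included: np.ndarray

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, dtype=bool)

    @property
    def size(self) -> int:
        return int(self.included.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.included)

    @classmethod
    def from_indices(cls, indices, p: int) -> "ModelIndicatorRow":
        v = np.zeros(p, dtype=bool)
        v[list(indices)] = True
        return cls(v)


@dataclass
class HyperParams:
    """Hyperparameters of the hierarchical selection model.

    ``d`` is the inverse-Wishart shape in the convention where ``E(Sigma_k) =
    h_k I_r / (d - 2)``, so d = 3 centres Sigma_k on h_k I_r.  ``h`` is the
    per-response error-variance scale (typically elicited empirically),
    ``(a_g, b_g)`` the inverse-gamma parameters of the shrinkage factor g,
    ``(a_omega, b_omega)`` the per-response Beta parameters of the sparsity
    level and ``(c_rho, d_rho)`` the shape/rate of the hotspot-propensity
    Gamma prior.
    """

    d: float = 3.0
    h: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    a_g: float = 0.5
    b_g: float = 1.0
    a_omega: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    b_omega: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    c_rho: float = 1.2
    d_rho: float = 1.2
    max_model_size: int = 15

    def __post_init__(self) -> None:
        self.h = np.atleast_1d(np.asarray(self.h, dtype=float))
        self.a_omega = np.atleast_1d(np.asarray(self.a_omega, dtype=float))
        self.b_omega = np.atleast_1d(np.asarray(self.b_omega, dtype=float))
        for name in ("d", "a_g", "b_g", "c_rho", "d_rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be strictly positive")
        if np.any(self.h <= 0):
            raise ValueError("h must be strictly positive")

    def size_cap(self, n: int) -> int:
        """Largest admissible |gamma_k| so that X_g'X_g stays invertible."""
        return int(min(n - 2, self.max_model_size))


def center_columns(Y: np.ndarray) -> np.ndarray:
    """Subtract column means (implements the flat intercept prior)."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows to center")
    return Y - Y.mean(axis=0, keepdims=True)


def _as_indices(gamma, p: int) -> np.ndarray:
    if isinstance(gamma, ModelIndicatorRow):
        return gamma.indices
    gamma = np.asarray(gamma)
    if gamma.dtype == bool or (gamma.ndim == 1 and gamma.size == p and set(np.unique(gamma)) <= {0, 1}):
        return np.flatnonzero(gamma)
    return gamma.astype(int)


def residual_quadratic(Y_c: np.ndarray, X: np.ndarray, gamma) -> np.ndarray:
    """Residual cross-product ``R(gamma) = Yc'Yc - Yc'X_g (X_g'X_g)^{-1} X_g'Yc``.

    For the empty model this is ``Yc'Yc``.  Raises
    :class:`SingularDesignError` when the selected columns are collinear.
    """
    Y_c = np.asarray(Y_c, dtype=float)
    X = np.asarray(X, dtype=float)
    idx = _as_indices(gamma, X.shape[1])
    YtY = Y_c.T @ Y_c
    if idx.size == 0:
        return YtY
    Xg = X[:, idx]
    K = Xg.T @ Xg
    XtY = Xg.T @ Y_c
    try:
        cf = cho_factor(K, lower=True)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(f"selected columns {idx.tolist()} are rank deficient") from exc
    if np.min(np.diag(cf[0])) < 1e-8 * max(1.0, float(np.max(np.diag(K)))) ** 0.5:
        raise SingularDesignError(f"selected columns {idx.tolist()} are numerically rank deficient")
    R = YtY - XtY.T @ cho_solve(cf, XtY)
    return 0.5 * (R + R.T)


class MarginalLikelihoodEngine:
    """Precomputed cross-products and cached evaluations of the marginal likelihood.

    Centers both Y_k and X once; caches ``log p(Y_k | gamma, g)`` per
    (response, model) at the current g, invalidating on g changes.
    """

    def __init__(self, X: np.ndarray, stacks: np.ndarray, hp: HyperParams, use_cache: bool = True):
        X = np.asarray(X, dtype=float)
        stacks = np.asarray(stacks, dtype=float)
        if stacks.ndim == 2:  # single response convenience
            stacks = stacks[None, :, :]
        self.n, self.p = X.shape
        self.q, n2, self.r = stacks.shape
        if n2 != self.n:
            raise ValueError("X and Y sample counts differ")
        self.hp = hp
        if hp.h.size == 1 and self.q > 1:
            self.h = np.full(self.q, float(hp.h[0]))
        elif hp.h.size == self.q:
            self.h = hp.h.astype(float)
        else:
            raise ValueError("h must be scalar or length q")
        self.Xc = center_columns(X)
        self.Yc = stacks - stacks.mean(axis=1, keepdims=True)
        self.XtX = self.Xc.T @ self.Xc
        self.XtY = np.einsum("ij,kil->kjl", self.Xc, self.Yc)  # (q, p, r)
        self.YtY = np.einsum("kil,kim->klm", self.Yc, self.Yc)  # (q, r, r)
        n, r, d = self.n, self.r, hp.d
        nu = d + r - 1.0  # inverse-Wishart dof in the standard convention
        self.expo = 0.5 * (nu + n - 1.0)  # = (d + n + r - 2) / 2
        self._const = (
            -0.5 * (n - 1) * r * np.log(np.pi)
            - 0.5 * r * np.log(n)
            + multigammaln(0.5 * (nu + n - 1.0), r)
            - multigammaln(0.5 * nu, r)
            + 0.5 * nu * r * np.log(self.h)
        )
        self._base = self.h[:, None, None] * np.eye(r) + self.YtY  # (q, r, r)
        # flattened copies for the scalar fast path (r <= 3)
        self._base_flat = self._base.reshape(self.q, r * r).tolist()
        self._const_list = [float(v) for v in np.atleast_1d(self._const)]
        # nested-list copies of the cross-products for the scalar fast paths
        # (reading numpy scalars one by one is ~5x slower than list access)
        self._xty_list = [[tuple(float(v) for v in self.XtY[k, j]) for j in range(self.p)]
                          for k in range(self.q)]
        self._xtx_list = [tuple(row) for row in self.XtX.tolist()]
        self.use_cache = use_cache
        # Q(k, gamma) = (L_K^{-1} X_g' Y_k)' (L_K^{-1} X_g' Y_k) does not depend
        # on g, so it survives g updates; only data changes would invalidate it.
        self._qcache: list[dict] = [dict() for _ in range(self.q)]
        self.size_cap = hp.size_cap(self.n)

    def invalidate(self) -> None:
        """Kept for API compatibility; cached quantities are g-independent."""

    def _fit_quadratic(self, k: int, gamma_idx: tuple[int, ...]) -> list:
        """The explained cross-product ``Y'X_g (X_g'X_g)^{-1} X_g'Y``.

        Returned (and cached) as the row-major flat list of the r x r matrix,
        which keeps the determinant evaluation in scalar arithmetic.
        """
        Qf = self._qcache[k].get(gamma_idx) if self.use_cache else None
        if Qf is None:
            m = len(gamma_idx)
            if m == 1:
                j = gamma_idx[0]
                a = self._xtx_list[j][j]
                if a ** 0.5 < 1e-6 * max(1.0, a) ** 0.5:
                    raise SingularDesignError(str(gamma_idx))
                b0 = self._xty_list[k][j]
                inv_a = 1.0 / a
                Qf = [bi * bj * inv_a for bi in b0 for bj in b0]
            elif m == 2:
                j0, j1 = gamma_idx
                x0, x1 = self._xtx_list[j0], self._xtx_list[j1]
                a, b, c = x0[j0], x1[j1], x0[j1]
                det = a * b - c * c
                thr = 1e-6 * max(1.0, max(a, b)) ** 0.5
                if a <= 0 or det <= 0 or min(a, det / a) ** 0.5 < thr:
                    raise SingularDesignError(str(gamma_idx))
                b0 = self._xty_list[k][j0]
                b1 = self._xty_list[k][j1]
                inv_det = 1.0 / det
                Qf = [
                    (b * x0 * y0 - c * (x0 * y1 + x1 * y0) + a * x1 * y1) * inv_det
                    for x0, x1 in zip(b0, b1)
                    for y0, y1 in zip(b0, b1)
                ]
            elif m == 3:
                j0, j1, j2 = gamma_idx
                x0, x1, x2 = self._xtx_list[j0], self._xtx_list[j1], self._xtx_list[j2]
                k00 = x0[j0]; k11 = x1[j1]; k22 = x2[j2]
                k01 = x0[j1]; k02 = x0[j2]; k12 = x1[j2]
                d1 = k00
                d2 = k00 * k11 - k01 * k01
                # adjugate of the symmetric 3x3 K
                a00 = k11 * k22 - k12 * k12
                a01 = k02 * k12 - k01 * k22
                a02 = k01 * k12 - k02 * k11
                a11 = k00 * k22 - k02 * k02
                a12 = k01 * k02 - k00 * k12
                a22 = k00 * k11 - k01 * k01
                det = k00 * a00 + k01 * a01 + k02 * a02
                # same guard as the Cholesky path: min squared pivot vs threshold
                thr2 = 1e-12 * max(1.0, k00, k11, k22)
                if d1 <= 0 or d2 <= 0 or det <= 0 or min(d1, d2 / d1, det / d2) < thr2:
                    raise SingularDesignError(str(gamma_idx))
                b0 = self._xty_list[k][j0]
                b1 = self._xty_list[k][j1]
                b2 = self._xty_list[k][j2]
                inv_det = 1.0 / det
                # C = K^{-1} B, then Q = B' C
                c0 = [(a00 * x + a01 * y + a02 * z) * inv_det for x, y, z in zip(b0, b1, b2)]
                c1 = [(a01 * x + a11 * y + a12 * z) * inv_det for x, y, z in zip(b0, b1, b2)]
                c2 = [(a02 * x + a12 * y + a22 * z) * inv_det for x, y, z in zip(b0, b1, b2)]
                Qf = [
                    x * cx + y * cy + z * cz
                    for x, y, z in zip(b0, b1, b2)
                    for cx, cy, cz in zip(c0, c1, c2)
                ]
            else:
                idx = np.asarray(gamma_idx, dtype=int)
                K = self.XtX[idx[:, None], idx]
                B = self.XtY[k][idx]  # (m, r)
                L, info = dpotrf(K, lower=1, clean=0, overwrite_a=1)
                if info != 0:
                    raise SingularDesignError(str(gamma_idx))
                maxdiag = max(self._xtx_list[j][j] for j in gamma_idx)
                if min(float(L[i, i]) for i in range(m)) < 1e-6 * max(1.0, maxdiag) ** 0.5:
                    raise SingularDesignError(str(gamma_idx))
                W, info = dtrtrs(L, B, lower=1)  # solve L W = B, (m, r)
                if info != 0:
                    raise SingularDesignError(str(gamma_idx))
                Qf = (W.T @ W).ravel().tolist()
            if self.use_cache:
                self._qcache[k][gamma_idx] = Qf
        return Qf

    def log_marginal(self, k: int, gamma_idx: tuple[int, ...], g: float) -> float:
        """Exact log p(Y_k | X, gamma, g); gamma given as a sorted index tuple."""
        m = len(gamma_idx)
        r = self.r
        if m > 0:
            qf = self._fit_quadratic(k, gamma_idx)
            c = g / (1.0 + g)
            s = [b - c * qv for b, qv in zip(self._base_flat[k], qf)]
        else:
            s = self._base_flat[k]
        if r == 1:
            det = s[0]
        elif r == 2:
            det = s[0] * s[3] - s[1] * s[2]
        elif r == 3:
            det = (
                s[0] * (s[4] * s[8] - s[5] * s[7])
                - s[1] * (s[3] * s[8] - s[5] * s[6])
                + s[2] * (s[3] * s[7] - s[4] * s[6])
            )
        else:
            S = np.asarray(s, dtype=float).reshape(r, r)
            sign, logdet = np.linalg.slogdet(S)
            if sign <= 0:
                raise np.linalg.LinAlgError("inner determinant matrix not positive definite")
            return float(self._const[k] - 0.5 * r * m * np.log1p(g) - self.expo * logdet)
        if det <= 0:
            raise np.linalg.LinAlgError("inner determinant matrix not positive definite")
        return self._const_list[k] - 0.5 * r * m * math.log1p(g) - self.expo * math.log(det)

    def log_marginal_nocache(self, k: int, gamma_idx: tuple[int, ...], g: float) -> float:
        """Alias of :meth:`log_marginal` (cached quantities are g-independent)."""
        return self.log_marginal(k, gamma_idx, g)


def log_marginal(Y_k: np.ndarray, X: np.ndarray, gamma, g: float, hp: HyperParams, k: int = 0) -> float:
    """Closed-form log marginal likelihood of response ``k`` (exact, with constants).

    Thin functional wrapper over :class:`MarginalLikelihoodEngine` for one-off
    evaluations; the sampler uses the engine directly.
    """
    if g <= 0:
        raise ValueError("g must be strictly positive")
    hk = hp.h[k] if hp.h.size > 1 else hp.h[0]
    hp1 = HyperParams(d=hp.d, h=np.array([hk]), a_g=hp.a_g, b_g=hp.b_g,
                      c_rho=hp.c_rho, d_rho=hp.d_rho, max_model_size=hp.max_model_size)
    eng = MarginalLikelihoodEngine(X, np.asarray(Y_k, dtype=float), hp1, use_cache=False)
    idx = tuple(_as_indices(gamma, X.shape[1]).tolist())
    return eng.log_marginal(0, idx, g)


def oracle_log_marginal_mc(
    Y_k: np.ndarray,
    X: np.ndarray,
    gamma,
    g: float,
    hp: HyperParams,
    n_draws: int = 100_000,
    seed: int = 0,
    k: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the marginal likelihood, for validating the closed form.

    Integrates the intercept analytically (centering), then averages the
    conditional likelihood over prior draws of (B_gamma, Sigma).  Returns
    ``(log estimate, standard error of the log)``.  Only intended for tiny
    problems (n <= 8, r <= 3, |gamma| <= 2).
    """
    Y_k = np.asarray(Y_k, dtype=float)
    X = np.asarray(X, dtype=float)
    n, r = Y_k.shape
    idx = _as_indices(gamma, X.shape[1])
    m = len(idx)
    if n > 8 or r > 3 or m > 2:
        raise ValueError("oracle restricted to n <= 8, r <= 3, |gamma| <= 2")
    hk = float(hp.h[k] if hp.h.size > 1 else hp.h[0])
    nu = hp.d + r - 1.0
    Yc = center_columns(Y_k)
    Xc = center_columns(X)
    rng = np.random.default_rng(seed)
    const = -0.5 * (n - 1) * r * np.log(2 * np.pi) - 0.5 * r * np.log(n)
    if m > 0:
        Xg = Xc[:, idx]
        K = Xg.T @ Xg
        Lk = np.linalg.cholesky(np.linalg.inv(K))
    logws = np.empty(n_draws)
    batch = 50_000
    done = 0
    while done < n_draws:
        b = min(batch, n_draws - done)
        Sig = invwishart.rvs(df=nu, scale=hk * np.eye(r), size=b, random_state=rng)
        Sig = np.asarray(Sig).reshape(b, r, r)
        if m > 0:
            Ls = np.linalg.cholesky(Sig)
            Gz = rng.standard_normal((b, m, r))
            B = np.sqrt(g) * np.einsum("ij,bjl,bml->bim", Lk, Gz, Ls)
            E = Yc[None, :, :] - np.einsum("ij,bjl->bil", Xg, B)
        else:
            E = np.broadcast_to(Yc, (b, n, r))
        EtE = np.einsum("bil,bim->blm", E, E)
        tr = np.einsum("bll->b", np.linalg.solve(Sig, EtE))
        _, ld = np.linalg.slogdet(Sig)
        logws[done : done + b] = const - 0.5 * (n - 1) * ld - 0.5 * tr
        done += b
    mx = np.max(logws)
    w = np.exp(logws - mx)
    mean_w = float(np.mean(w))
    est = mx + np.log(mean_w)
    se = float(np.std(w, ddof=1) / (mean_w * np.sqrt(n_draws)))
    return est, se
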