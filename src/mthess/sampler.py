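"""Evolutionary Monte Carlo sampler over (Gamma, omega, rho, g).

A population of C chains runs at increasing temperatures t_1 = 1 < t_2 < ...
Each sweep updates a random subset of responses: per chain a local
Metropolis-Hastings move on the response's inclusion row (add / delete / swap
of one marker), then a genetic crossover move that recombines the row between
two chains selected with Boltzmann weights, then the per-response sparsity
level omega_k.  After the response loop the hotspot propensities rho_j are
updated in every chain, a full-state temperature exchange between an adjacent
chain pair is proposed, per-response (gamma_k, omega_k) block swaps between
adjacent chains are proposed, and the shared shrinkage factor g is updated
against the cold chain's posterior.  Only the cold (t = 1) chain is recorded.

Proposal step sizes (omega, rho, g random walks) are adapted during burn-in
only, so the recorded portion of the run is a fixed-kernel Markov chain.  The
temperature ladder is a fixed geometric one by default (see LadderConfig).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln

from .likelihood import HyperParams, MarginalLikelihoodEngine, SingularDesignError
from .priors import log_prior_g, log_prior_gamma_row

logger = logging.getLogger(__name__)

__all__ = [
    "LadderConfig",
    "SamplerConfig",
    "ChainState",
    "PosteriorTrace",
    "EMCSampler",
    "run_sampler",
    "exact_enumeration",
    "tune_ladder",
]


@dataclass
class LadderConfig:
    """Temperature ladder: geometric, optionally tuned toward a target swap rate.

    Tuning is off by default: the exchange move swaps *full* chain states, and
    with many responses the total log posterior differs between chains by far
    more than one unit, so no meaningful temperature spacing can reach a high
    swap target -- the tuner then collapses the ladder toward 1 and removes
    tempering entirely (observed: temperatures [1, 1.01, 1.02] and chains
    locked in metastable modes). With a fixed geometric ladder the hot chains
    stay genuinely hot and the per-row crossover move carries their
    discoveries down to the cold chain.
    """

    n_chains: int = 3
    temperatures: np.ndarray | None = None
    # the ratio is deliberately mild: tempering scales down the sparsity
    # prior's per-marker inclusion penalty (|logit| ~ 5-6 at p ~ 300) along
    # with the likelihood, so hot chains under an aggressive ladder (ratio 2)
    # saturate at the model-size cap -- slow, and useless as exploration
    # partners (measured: mean |gamma_k| 14.5-14.8 of cap 15 at T = 2 and 4,
    # block-swap acceptance 2%). At ratio 1.1 the chains stay sparse
    # (mean sizes ~2 / 3 / 6) and block-swap/crossover acceptance is 36%/42%.
    init_ratio: float = 1.1
    adapt_interval: int = 100
    target_swap_rate: float = 0.5
    tune: bool = False

    def make_temperatures(self) -> np.ndarray:
        if self.temperatures is not None:
            t = np.asarray(self.temperatures, dtype=float)
            if t[0] != 1.0 or np.any(np.diff(t) <= 0):
                raise ValueError("temperatures must start at 1 and increase strictly")
            if len(t) != self.n_chains:
                raise ValueError("temperatures length must equal n_chains")
            return t
        return self.init_ratio ** np.arange(self.n_chains, dtype=float)


@dataclass
class SamplerConfig:
    n_sweeps: int = 15_000
    burn_in: int = 5_000
    seed: int = 0
    response_update_fraction: float = 1.0
    move_probabilities: dict = field(default_factory=lambda: {"add": 0.35, "delete": 0.35, "swap": 0.30})
    record_full_gamma: bool = False
    thin: int = 10
    update_omega: bool = True
    update_rho: bool = True
    update_g: bool = True
    crossover: bool = True
    exchange: bool = True
    block_exchange: bool = True
    debug_checks: bool = False
    log_every: int = 500

    def validate(self) -> None:
        if not 0 <= self.burn_in < self.n_sweeps:
            raise ValueError("need 0 <= burn_in < n_sweeps")
        if not 0 < self.response_update_fraction <= 1:
            raise ValueError("response_update_fraction must lie in (0, 1]")
        tot = sum(self.move_probabilities.get(m, 0.0) for m in ("add", "delete", "swap"))
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("move probabilities must sum to 1")


@dataclass
class ChainState:
    """State of one tempered chain: inclusion matrix, omega, rho, cached likelihoods."""

    gamma: np.ndarray  # (q, p) bool
    rows: list  # list of sorted index tuples, one per response
    omega: np.ndarray  # (q,)
    rho: np.ndarray  # (p,)
    log_marginals: np.ndarray  # (q,) cached at the shared g
    temperature: float

    def refresh_prior(self, k: int | None = None) -> None:
        """Recompute the cached Bernoulli prior tables (row k, or all rows).

        Caches log(w), log(1 - w), their per-row inclusion log-odds and the
        all-excluded row log prior for w = omega_k rho_j; every prior lookup in
        the move kernels reads these tables instead of recomputing logs.
        """
        with np.errstate(divide="ignore"):
            if k is None:
                w = np.outer(self.omega, self.rho)
                self.logw = np.log(w)
                self.log1mw = np.log1p(-w)
                self.logit_w = self.logw - self.log1mw
                self.base_row = self.log1mw.sum(axis=1)
                self.row_prior = self.base_row + np.where(
                    self.gamma, self.logit_w, 0.0).sum(axis=1)
            else:
                wk = self.omega[k] * self.rho
                self.logw[k] = np.log(wk)
                self.log1mw[k] = np.log1p(-wk)
                self.logit_w[k] = self.logw[k] - self.log1mw[k]
                self.base_row[k] = self.log1mw[k].sum()
                self.row_prior[k] = self.base_row[k] + float(
                    self.logit_w[k][self.gamma[k]].sum())


@dataclass
class PosteriorTrace:
    """Recorded output of the cold chain after burn-in."""

    gamma_inclusion_counts: np.ndarray  # (q, p)
    n_recorded: int
    g_samples: np.ndarray
    omega_samples: np.ndarray  # (n_thin, q)
    rho_samples: np.ndarray  # (n_thin, p)
    visited_models: list  # per response: dict {row tuple: visit count}
    acceptance_stats: dict
    temperatures: np.ndarray
    gamma_samples: list | None = None  # per recorded sweep: list of row tuples

    @property
    def omega_mean(self) -> np.ndarray:
        return self.omega_samples.mean(axis=0)

    @property
    def rho_mean(self) -> np.ndarray:
        return self.rho_samples.mean(axis=0)

    @property
    def g_mean(self) -> float:
        return float(np.mean(self.g_samples))


def tune_ladder(observed_rate: float, ladder: LadderConfig, current_ratio: float) -> float:
    """Rescale the geometric ladder ratio toward the target swap rate.

    A low observed rate pulls temperatures closer together (ratio shrinks);
    returns the new common ratio (t_1 stays 1).
    """
    ratio = current_ratio * float(np.exp(observed_rate - ladder.target_swap_rate))
    return max(1.01, ratio)


class EMCSampler:
    """Evolutionary Monte Carlo over the hierarchical selection posterior."""

    def __init__(
        self,
        engine: MarginalLikelihoodEngine,
        hp: HyperParams,
        cfg: SamplerConfig,
        ladder: LadderConfig | None = None,
        *,
        omega0: np.ndarray | None = None,
        rho0: np.ndarray | None = None,
        g0: float | None = None,
        init_gamma: np.ndarray | None = None,
    ):
        cfg.validate()
        self.engine = engine
        self.hp = hp
        self.cfg = cfg
        self.ladder = ladder or LadderConfig()
        self.q, self.p, self.n, self.r = engine.q, engine.p, engine.n, engine.r
        self.size_cap = engine.size_cap
        self.rng = np.random.default_rng(cfg.seed)
        self.temperatures = self.ladder.make_temperatures()
        self.ratio = self.temperatures[1] / self.temperatures[0] if len(self.temperatures) > 1 else self.ladder.init_ratio
        a_om = np.broadcast_to(hp.a_omega, (self.q,))
        b_om = np.broadcast_to(hp.b_omega, (self.q,))
        self.a_omega, self.b_omega = a_om.astype(float), b_om.astype(float)
        omega0 = np.broadcast_to(
            np.atleast_1d(omega0 if omega0 is not None else a_om / (a_om + b_om)), (self.q,)
        ).astype(float)
        rho0 = np.broadcast_to(np.atleast_1d(rho0 if rho0 is not None else 1.0), (self.p,)).astype(float)
        if np.max(omega0) * np.max(rho0) > 1.0:
            raise ValueError("initial state violates omega_k * rho_j <= 1")
        self.g = float(g0 if g0 is not None else hp.b_g / (hp.a_g + 1.0))  # prior mode
        self.chains: list[ChainState] = []
        for c, t in enumerate(self.temperatures):
            if init_gamma is None:
                gam = np.zeros((self.q, self.p), dtype=bool)
            else:
                gam = np.asarray(init_gamma, dtype=bool).copy()
            rows = [tuple(np.flatnonzero(gam[k]).tolist()) for k in range(self.q)]
            lm = np.array([self.engine.log_marginal(k, rows[k], self.g) for k in range(self.q)])
            state = ChainState(gam, rows, omega0.copy(), rho0.copy(), lm, float(t))
            state.refresh_prior()
            self.chains.append(state)
        # normalizing constants of the omega and rho priors (fixed hyperparameters)
        self._om_lognorm = float(-betaln(self.a_omega, self.b_omega).sum())
        self._rho_lognorm = float(
            self.p * (hp.c_rho * np.log(hp.d_rho) - gammaln(hp.c_rho))
        )
        # proposal step sizes, Robbins-Monro adapted during burn-in
        self.step_omega = np.full(len(self.chains), 1.0)
        self.step_rho = np.full(len(self.chains), 0.5)
        self.step_g = 0.5
        self.acc = {m: [0, 0] for m in ("add", "delete", "swap", "crossover", "exchange",
                                        "block_exchange", "omega", "rho", "g")}
        self._window = {m: [0, 0] for m in ("omega", "rho", "g", "exchange")}

    # ------------------------------------------------------------------ moves

    def local_move(self, state: ChainState, k: int) -> None:
        """One MH add/delete/swap update of row gamma_k in one chain."""
        mp = self.cfg.move_probabilities
        u = self.rng.random()
        move = "add" if u < mp["add"] else ("delete" if u < mp["add"] + mp["delete"] else "swap")
        self.acc[move][1] += 1
        row = state.rows[k]
        n1 = len(row)
        mask = state.gamma[k]
        logit = state.logit_w[k]
        if move == "add":
            if n1 >= self.size_cap or n1 >= self.p:
                return
            # rejection sampling = uniform over the excluded markers
            j = int(self.rng.integers(self.p))
            while mask[j]:
                j = int(self.rng.integers(self.p))
            new_row = tuple(sorted(row + (j,)))
            d_prior = logit[j]
            log_prop = math.log(mp["delete"] / mp["add"] * (self.p - n1) / (n1 + 1.0))
        elif move == "delete":
            if n1 == 0:
                return
            j = row[self.rng.integers(n1)]
            new_row = tuple(x for x in row if x != j)
            d_prior = -logit[j]
            log_prop = math.log(mp["add"] / mp["delete"] * n1 / (self.p - n1 + 1.0))
        else:  # swap
            if n1 == 0 or n1 >= self.p:
                return
            j_out = row[self.rng.integers(n1)]
            j_in = int(self.rng.integers(self.p))
            while mask[j_in]:
                j_in = int(self.rng.integers(self.p))
            new_row = tuple(sorted([x for x in row if x != j_out] + [j_in]))
            if math.isfinite(logit[j_in]) and math.isfinite(logit[j_out]):
                d_prior = logit[j_in] - logit[j_out]
            else:
                d_prior = -np.inf
            log_prop = 0.0
        try:
            lm_new = self.engine.log_marginal(k, new_row, self.g)
        except SingularDesignError:
            return
        log_alpha = (lm_new - state.log_marginals[k] + d_prior) / state.temperature + log_prop
        if log_alpha >= 0.0 or math.log(self.rng.random()) < log_alpha:
            self.acc[move][0] += 1
            self._apply_row(state, k, new_row, lm_new, float(state.row_prior[k] + d_prior))

    def _apply_row(self, state: ChainState, k: int, new_row: tuple, lm_new: float,
                   prior_new: float) -> None:
        state.gamma[k, :] = False
        if new_row:
            state.gamma[k, list(new_row)] = True
        state.rows[k] = new_row
        state.log_marginals[k] = lm_new
        state.row_prior[k] = prior_new

    def _row_logprior_idx(self, state: ChainState, k: int, row: tuple) -> float:
        total = float(state.base_row[k])
        lw = state.logit_w[k]
        for j in row:
            total += lw[j]
        return total

    def _row_score(self, state: ChainState, k: int) -> float:
        return float(state.log_marginals[k] + state.row_prior[k])

    def crossover_move(self, k: int) -> None:
        """Genetic crossover of row k between two Boltzmann-selected chains."""
        C = len(self.chains)
        if C < 2:
            return
        self.acc["crossover"][1] += 1
        first = self.chains[0].rows[k]
        if all(s.rows[k] == first for s in self.chains[1:]):
            # identical parents: any crossover is accepted and changes nothing
            self.acc["crossover"][0] += 1
            return
        scores = [self._row_score(s, k) / s.temperature for s in self.chains]

        def sel_probs(sc):
            mx = max(sc)
            z = [math.exp(v - mx) for v in sc]
            tot = sum(z)
            return [v / tot for v in z]

        pr_cur = sel_probs(scores)
        u = self.rng.random()
        acc_p = 0.0
        c1 = C - 1
        for c in range(C):
            acc_p += pr_cur[c]
            if u < acc_p:
                c1 = c
                break
        others = [c for c in range(C) if c != c1]
        c2 = int(others[self.rng.integers(C - 1)])
        s1, s2 = self.chains[c1], self.chains[c2]
        a, b = s1.rows[k], s2.rows[k]
        if a == b:
            self.acc["crossover"][0] += 1
            return
        set_a, set_b = set(a), set(b)
        if self.p > 1 and self.rng.random() < 0.5:  # one-point (needs >= 2 loci)
            cut = int(self.rng.integers(1, self.p))
            r1 = tuple(sorted([j for j in a if j < cut] + [j for j in b if j >= cut]))
            r2 = tuple(sorted([j for j in b if j < cut] + [j for j in a if j >= cut]))
        else:  # uniform: loci outside the symmetric difference are common to both
            o1 = list(set_a & set_b)
            o2 = list(o1)
            for j in sorted(set_a ^ set_b):
                if self.rng.random() < 0.5:
                    o1.append(j)
                else:
                    o2.append(j)
            r1, r2 = tuple(sorted(o1)), tuple(sorted(o2))
        if r1 == a:  # offspring identical to parents: accepted no-op
            self.acc["crossover"][0] += 1
            return
        if len(r1) > self.size_cap or len(r2) > self.size_cap:
            return
        try:
            lm1 = self.engine.log_marginal(k, r1, self.g)
            lm2 = self.engine.log_marginal(k, r2, self.g)
        except SingularDesignError:
            return
        pr1 = self._row_logprior_idx(s1, k, r1)
        pr2 = self._row_logprior_idx(s2, k, r2)
        f1_new = (lm1 + pr1) / s1.temperature
        f2_new = (lm2 + pr2) / s2.temperature
        f1_old, f2_old = scores[c1], scores[c2]
        # selection-probability correction for detailed balance
        scores_new = list(scores)
        scores_new[c1], scores_new[c2] = f1_new, f2_new
        pr_new = sel_probs(scores_new)
        q_fwd = pr_cur[c1] + pr_cur[c2]
        q_rev = pr_new[c1] + pr_new[c2]
        log_alpha = (f1_new - f1_old) + (f2_new - f2_old) + math.log(q_rev) - math.log(q_fwd)
        if log_alpha >= 0.0 or math.log(self.rng.random()) < log_alpha:
            self.acc["crossover"][0] += 1
            self._apply_row(s1, k, r1, lm1, pr1)
            self._apply_row(s2, k, r2, lm2, pr2)

    def exchange_move(self) -> None:
        """Propose swapping the full states of an adjacent temperature pair."""
        C = len(self.chains)
        if C < 2:
            return
        self.acc["exchange"][1] += 1
        self._window["exchange"][1] += 1
        a = int(self.rng.integers(C - 1))
        sa, sb = self.chains[a], self.chains[a + 1]
        fa, fb = self._total_logpost(sa), self._total_logpost(sb)
        log_alpha = (fb - fa) * (1.0 / sa.temperature - 1.0 / sb.temperature)
        if np.log(self.rng.random()) < log_alpha:
            self.acc["exchange"][0] += 1
            self._window["exchange"][0] += 1
            ta, tb = sa.temperature, sb.temperature
            self.chains[a], self.chains[a + 1] = sb, sa
            sb.temperature, sa.temperature = ta, tb

    def block_exchange_move(self) -> None:
        """Per-response tempered swap of the (gamma_k, omega_k) block.

        The full-state exchange is essentially never accepted once q is large
        (the total log posteriors of two chains differ by far more than one
        unit), which leaves the cold chain unable to inherit anything from the
        tempered chains. The (gamma_k, omega_k) blocks are conditionally
        independent across responses given (rho, g), so swapping one block
        between an adjacent pair is a valid Metropolis move on the product
        space with a per-response energy gap small enough to accept — and it
        breaks the metastable traps where an inflated omega_k and an oversized
        row sustain each other. All responses are proposed in one vectorized
        pass per adjacent pair (independent accept/reject decisions).
        """
        C = len(self.chains)
        if C < 2:
            return
        a_k, b_k = self.a_omega, self.b_omega
        for c in range(C - 1):
            s0, s1 = self.chains[c], self.chains[c + 1]
            self.acc["block_exchange"][1] += self.q
            gam0, gam1 = s0.gamma, s1.gamma
            lm0, lm1 = s0.log_marginals, s1.log_marginals
            # cached row priors under each chain's own (omega, rho)
            p0_cur, p1_cur = s0.row_prior, s1.row_prior
            same_hyper = np.array_equal(s0.omega, s1.omega) and np.array_equal(s0.rho, s1.rho)
            inv_dt = 1.0 / s0.temperature - 1.0 / s1.temperature
            if same_hyper:
                # pure row swap: priors under identical tables, omega terms cancel
                delta = (lm1 + p1_cur - lm0 - p0_cur) * inv_dt
                accept = np.log(self.rng.random(self.q)) < delta
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    # row priors after the swap: other chain's (gamma_k, omega_k)
                    # under this chain's rho
                    w0 = np.outer(s1.omega, s0.rho)
                    l1mw0 = np.log1p(-w0)
                    p0_new = l1mw0.sum(axis=1) + np.where(
                        gam1, np.log(w0) - l1mw0, 0.0).sum(axis=1)
                    w1 = np.outer(s0.omega, s1.rho)
                    l1mw1 = np.log1p(-w1)
                    p1_new = l1mw1.sum(axis=1) + np.where(
                        gam0, np.log(w1) - l1mw1, 0.0).sum(axis=1)
                    beta0 = (a_k - 1.0) * np.log(s0.omega) + (b_k - 1.0) * np.log1p(-s0.omega)
                    beta1 = (a_k - 1.0) * np.log(s1.omega) + (b_k - 1.0) * np.log1p(-s1.omega)
                    delta = (
                        (lm1 + p0_new + beta1 - lm0 - p0_cur - beta0) / s0.temperature
                        + (lm0 + p1_new + beta0 - lm1 - p1_cur - beta1) / s1.temperature
                    )
                    valid = (s1.omega * float(np.max(s0.rho)) <= 1.0) & (
                        s0.omega * float(np.max(s1.rho)) <= 1.0
                    )
                    accept = valid & (np.log(self.rng.random(self.q)) < delta)
            n_acc = int(accept.sum())
            self.acc["block_exchange"][0] += n_acc
            if n_acc == 0:
                continue
            ks = np.flatnonzero(accept)
            rows_block = gam0[ks].copy()
            gam0[ks] = gam1[ks]
            gam1[ks] = rows_block
            for k in ks:
                s0.rows[k], s1.rows[k] = s1.rows[k], s0.rows[k]
            lm_block = lm0[ks].copy()
            lm0[ks] = lm1[ks]
            lm1[ks] = lm_block
            if same_hyper:
                pr_block = s0.row_prior[ks].copy()
                s0.row_prior[ks] = s1.row_prior[ks]
                s1.row_prior[ks] = pr_block
                continue
            om_block = s0.omega[ks].copy()
            s0.omega[ks] = s1.omega[ks]
            s1.omega[ks] = om_block
            for s in (s0, s1):
                with np.errstate(divide="ignore"):
                    w = s.omega[ks, None] * s.rho[None, :]
                    s.logw[ks] = np.log(w)
                    s.log1mw[ks] = np.log1p(-w)
                    s.logit_w[ks] = s.logw[ks] - s.log1mw[ks]
                    s.base_row[ks] = s.log1mw[ks].sum(axis=1)
                    s.row_prior[ks] = s.base_row[ks] + np.where(
                        s.gamma[ks], s.logit_w[ks], 0.0).sum(axis=1)

    def _total_logpost(self, state: ChainState) -> float:
        """Untempered log posterior of a chain state (g prior excluded: shared)."""
        row_pri = state.row_prior.sum()
        om_pri = (
            np.sum((self.a_omega - 1.0) * np.log(state.omega)
                   + (self.b_omega - 1.0) * np.log1p(-state.omega))
            + self._om_lognorm
        )
        rho_pri = (
            np.sum((self.hp.c_rho - 1.0) * np.log(state.rho) - self.hp.d_rho * state.rho)
            + self._rho_lognorm
        )
        return float(state.log_marginals.sum() + row_pri + om_pri + rho_pri)

    def update_omega(self, ci: int, ks: np.ndarray) -> None:
        """Logit random-walk MH on omega_k for rows ``ks`` (independent conditionals)."""
        state = self.chains[ci]
        ks = np.asarray(ks, dtype=int)
        m = ks.size
        om = state.omega[ks]
        z = np.log(om) - np.log1p(-om)
        z_new = z + self.step_omega[ci] * self.rng.standard_normal(m)
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            om_new = 1.0 / (1.0 + np.exp(-z_new))
            self.acc["omega"][1] += m
            self._window["omega"][1] += m
            valid = om_new * float(np.max(state.rho)) <= 1.0
            gk = state.gamma[ks]  # (m, p)
            n1 = gk.sum(axis=1)
            a_k, b_k = self.a_omega[ks], self.b_omega[ks]
            # sum over excluded markers of log(1 - o rho_j), current value from cache
            s_out_cur = state.base_row[ks] - np.where(gk, state.log1mw[ks], 0.0).sum(axis=1)
            s_out_new = np.where(gk, 0.0, np.log1p(-np.outer(om_new, state.rho))).sum(axis=1)

            def cond(o, s_out):
                # Bernoulli row terms plus the Beta(a, b) kernel (constant cancels)
                return n1 * np.log(o) + s_out + (a_k - 1.0) * np.log(o) + (b_k - 1.0) * np.log1p(-o)

            # Jacobian of the logit transform: log|do/dz| = log o + log(1-o)
            log_alpha = (cond(om_new, s_out_new) - cond(om, s_out_cur)) / state.temperature
            log_alpha += np.log(om_new) + np.log1p(-om_new) - np.log(om) - np.log1p(-om)
            accept = valid & (np.log(self.rng.random(m)) < log_alpha)
        n_acc = int(accept.sum())
        self.acc["omega"][0] += n_acc
        self._window["omega"][0] += n_acc
        if n_acc:
            rows = ks[accept]
            state.omega[rows] = om_new[accept]
            with np.errstate(divide="ignore"):
                w = state.omega[rows, None] * state.rho[None, :]
                state.logw[rows] = np.log(w)
                state.log1mw[rows] = np.log1p(-w)
                state.logit_w[rows] = state.logw[rows] - state.log1mw[rows]
                state.base_row[rows] = state.log1mw[rows].sum(axis=1)
                state.row_prior[rows] = state.base_row[rows] + np.where(
                    state.gamma[rows], state.logit_w[rows], 0.0).sum(axis=1)

    def update_rho(self, ci: int) -> None:
        """Vectorized log random-walk MH on all rho_j (conditionally independent)."""
        state = self.chains[ci]
        rho = state.rho
        rho_new = rho * np.exp(self.step_rho[ci] * self.rng.standard_normal(self.p))
        self.acc["rho"][1] += self.p
        self._window["rho"][1] += self.p
        max_om = float(np.max(state.omega))
        ok = rho_new * max_om <= 1.0
        gam = state.gamma
        counts = gam.sum(axis=0)  # number of responses including marker j

        def cond(r):
            # sum_k [gamma_kj log(om_k r_j) + (1-gamma_kj) log(1 - om_k r_j)]
            with np.errstate(divide="ignore", invalid="ignore"):
                t1 = counts * np.log(r)
                m = 1.0 - np.outer(state.omega, r)
                t2 = np.where(gam, 0.0, np.log(m)).sum(axis=0)
            # Gamma(c, rate d) log kernel (normalizing constant cancels in the ratio)
            return t1 + t2 + (self.hp.c_rho - 1.0) * np.log(r) - self.hp.d_rho * r

        log_alpha = (cond(rho_new) - cond(rho)) / state.temperature + np.log(rho_new) - np.log(rho)
        accept = ok & (np.log(self.rng.random(self.p)) < log_alpha)
        n_acc = int(accept.sum())
        self.acc["rho"][0] += n_acc
        self._window["rho"][0] += n_acc
        if n_acc:
            state.rho = np.where(accept, rho_new, rho)
            state.refresh_prior()

    def update_g(self) -> None:
        """Log random-walk MH on the shared g against the cold chain's posterior."""
        self.acc["g"][1] += 1
        self._window["g"][1] += 1
        cold = self.chains[0]
        g_new = self.g * float(np.exp(self.step_g * self.rng.standard_normal()))
        lm_new = np.array(
            [self.engine.log_marginal_nocache(k, cold.rows[k], g_new) for k in range(self.q)]
        )
        log_alpha = (
            lm_new.sum()
            - cold.log_marginals.sum()
            + log_prior_g(g_new, self.hp.a_g, self.hp.b_g)
            - log_prior_g(self.g, self.hp.a_g, self.hp.b_g)
            + np.log(g_new)
            - np.log(self.g)
        )
        if np.log(self.rng.random()) < log_alpha:
            self.acc["g"][0] += 1
            self._window["g"][0] += 1
            self.g = g_new
            cold.log_marginals = lm_new
            for s in self.chains[1:]:
                s.log_marginals = np.array(
                    [self.engine.log_marginal_nocache(k, s.rows[k], g_new) for k in range(self.q)]
                )
            self.engine.invalidate()

    # ------------------------------------------------------------------- run

    def _adapt(self) -> None:
        for name, step_attr in (("omega", "step_omega"), ("rho", "step_rho")):
            acc, tot = self._window[name]
            if tot > 0:
                rate = acc / tot
                setattr(self, step_attr, np.clip(getattr(self, step_attr) * np.exp(0.7 * (rate - 0.4)), 1e-3, 20.0))
        acc, tot = self._window["g"]
        if tot > 0:
            self.step_g = float(np.clip(self.step_g * np.exp(0.7 * (acc / tot - 0.4)), 1e-3, 10.0))
        acc, tot = self._window["exchange"]
        if self.ladder.tune and tot > 0 and len(self.chains) > 1:
            self.ratio = tune_ladder(acc / tot, self.ladder, self.ratio)
            self.temperatures = self.ratio ** np.arange(len(self.chains), dtype=float)
            for s, t in zip(self.chains, self.temperatures):
                s.temperature = float(t)
        for m in self._window:
            self._window[m] = [0, 0]

    def _debug_validate(self) -> None:
        for s in self.chains:
            assert float(np.max(s.omega)) * float(np.max(s.rho)) <= 1.0 + 1e-12
            with np.errstate(divide="ignore"):
                w = np.outer(s.omega, s.rho)
                assert np.allclose(s.base_row, np.log1p(-w).sum(axis=1))
                assert np.allclose(s.logit_w, np.log(w) - np.log1p(-w), equal_nan=True)
                expect_pr = s.base_row + np.where(s.gamma, s.logit_w, 0.0).sum(axis=1)
                assert np.allclose(s.row_prior, expect_pr, atol=1e-7), "row_prior drift"
            for k in range(self.q):
                lm = self.engine.log_marginal_nocache(k, s.rows[k], self.g)
                assert abs(lm - s.log_marginals[k]) < 1e-8, (k, lm, s.log_marginals[k])

    def run(self) -> PosteriorTrace:
        cfg = self.cfg
        q, p = self.q, self.p
        counts = np.zeros((q, p))
        g_samples: list[float] = []
        om_samples: list[np.ndarray] = []
        rho_samples: list[np.ndarray] = []
        visited: list[dict] = [dict() for _ in range(q)]
        gamma_samples: list | None = [] if cfg.record_full_gamma else None
        n_rec = 0
        n_upd = max(1, int(np.ceil(cfg.response_update_fraction * q)))
        for t in range(cfg.n_sweeps):
            ks = self.rng.permutation(q)[:n_upd] if n_upd < q else range(q)
            for k in ks:
                for state in self.chains:
                    self.local_move(state, k)
                if cfg.crossover:
                    self.crossover_move(k)
            if cfg.update_omega:
                ks_arr = np.asarray(ks, dtype=int)
                for ci in range(len(self.chains)):
                    self.update_omega(ci, ks_arr)
            if cfg.update_rho:
                for ci in range(len(self.chains)):
                    self.update_rho(ci)
            if cfg.exchange:
                self.exchange_move()
            if cfg.block_exchange:
                self.block_exchange_move()
            if cfg.update_g:
                self.update_g()
            in_burn = t < cfg.burn_in
            if in_burn and (t + 1) % self.ladder.adapt_interval == 0:
                self._adapt()
            if cfg.debug_checks and (t + 1) % 100 == 0:
                self._debug_validate()
            if not in_burn:
                cold = self.chains[0]
                counts += cold.gamma
                g_samples.append(self.g)
                n_rec += 1
                for k in range(q):
                    visited[k][cold.rows[k]] = visited[k].get(cold.rows[k], 0) + 1
                if n_rec % cfg.thin == 0:
                    om_samples.append(cold.omega.copy())
                    rho_samples.append(cold.rho.copy())
                if gamma_samples is not None:
                    gamma_samples.append(list(cold.rows))
            if cfg.log_every and (t + 1) % cfg.log_every == 0:
                rates = {m: (a / max(1, b)) for m, (a, b) in self.acc.items()}
                logger.info("sweep %d/%d g=%.3f acc=%s", t + 1, cfg.n_sweeps, self.g,
                            {m: round(v, 3) for m, v in rates.items()})
        if not om_samples:  # ensure at least one thinned record
            cold = self.chains[0]
            om_samples.append(cold.omega.copy())
            rho_samples.append(cold.rho.copy())
        return PosteriorTrace(
            gamma_inclusion_counts=counts,
            n_recorded=n_rec,
            g_samples=np.array(g_samples),
            omega_samples=np.array(om_samples),
            rho_samples=np.array(rho_samples),
            visited_models=visited,
            acceptance_stats={m: tuple(v) for m, v in self.acc.items()},
            temperatures=self.temperatures.copy(),
            gamma_samples=gamma_samples,
        )


def run_sampler(
    X,
    stacks,
    hp: HyperParams,
    cfg: SamplerConfig,
    ladder: LadderConfig | None = None,
    *,
    omega0=None,
    rho0=None,
    g0=None,
    init_gamma=None,
    engine: MarginalLikelihoodEngine | None = None,
) -> PosteriorTrace:
    """Run the EMC sampler on a genotype matrix and response stacks.

    ``X`` may be an (n, p) array or a :class:`~mthess.data.GenotypePanel`;
    ``stacks`` an (q, n, r) array or a :class:`~mthess.data.ResponsePanel`.
    Fully reproducible given ``cfg.seed``.
    """
    Xv = getattr(X, "values", X)
    Sv = getattr(stacks, "stacks", stacks)
    if engine is None:
        engine = MarginalLikelihoodEngine(Xv, Sv, hp)
    sampler = EMCSampler(engine, hp, cfg, ladder, omega0=omega0, rho0=rho0, g0=g0, init_gamma=init_gamma)
    return sampler.run()


def exact_enumeration(
    X,
    stacks,
    hp: HyperParams,
    omega,
    rho,
    g: float,
    max_size: int | None = None,
) -> np.ndarray:
    """Exact MPPI matrix by summing posterior mass over all models per response.

    With omega, rho and g fixed the responses are independent, so each row's
    posterior is an exhaustive sum over subsets up to the size cap.  Guarded to
    p <= 12.
    """
    Xv = getattr(X, "values", X)
    Sv = getattr(stacks, "stacks", stacks)
    if Sv.ndim == 2:
        Sv = Sv[None, :, :]
    q, _, _ = Sv.shape
    p = Xv.shape[1]
    if p > 12:
        raise ValueError("exact enumeration limited to p <= 12")
    engine = MarginalLikelihoodEngine(Xv, Sv, hp)
    cap = engine.size_cap if max_size is None else min(max_size, engine.size_cap)
    omega = np.broadcast_to(np.atleast_1d(omega), (q,)).astype(float)
    rho = np.broadcast_to(np.atleast_1d(rho), (p,)).astype(float)
    mppi = np.zeros((q, p))
    for k in range(q):
        logpost = []
        models = []
        for size in range(cap + 1):
            for comb in itertools.combinations(range(p), size):
                mask = np.zeros(p, dtype=bool)
                mask[list(comb)] = True
                try:
                    lm = engine.log_marginal(k, comb, g)
                except SingularDesignError:
                    continue
                logpost.append(lm + log_prior_gamma_row(mask, omega[k], rho))
                models.append(mask)
        logpost = np.array(logpost)
        wts = np.exp(logpost - logpost.max())
        wts /= wts.sum()
        for wt, mask in zip(wts, models):
            mppi[k, mask] += wt
    return mppi
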