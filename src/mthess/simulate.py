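"""Synthetic multi-condition eQTL data with stored ground truth.

Genotypes emulate a two-strain recombinant-inbred (RI) panel: binary dosages
following a two-state Markov chain along each chromosome (recombination
probability ``switch_prob`` between adjacent markers), independent across
chromosomes and individuals, with redundant (identical or complementary)
markers removed — reproducing the block-wise linkage disequilibrium of a real
RI panel qualitatively.

Responses follow a linear model per condition,

    Y_l = X B + E_l + E_shared,

with the coefficient matrix B shared across conditions (associations present
in every condition), per-condition noise sd ``sigma_l`` and a shared noise
component ``sigma_shared`` common to all conditions, so the total noise sd is
``sigma_l_total = sqrt(sigma_l^2 + sigma_shared^2)`` and the between-condition
residual correlation is driven by the shared component.

Two association patterns are provided: ``hotspots`` (six hotspot markers with
10, 10, 20, 20, 30 and 30 associated responses) and ``cis_trans`` (the same
hotspots plus 10 strong cis associations, half on otherwise unassociated
responses).  Effect sizes are drawn ``lambda_kj ~ N(mu_class, lambda_sd^2)``
with ``mu_cis = 0.6`` and ``mu_trans = 0.15`` by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import GenotypePanel, ResponsePanel, dedupe_markers

__all__ = ["SimConfig", "SimTruth", "simulate_ri_genotypes", "build_pattern",
           "simulate_effects", "simulate_responses", "simulate_dataset",
           "CLASS_NEGATIVE", "CLASS_CIS_ISOLATED", "CLASS_CIS_OTHER", "CLASS_TRANS"]

CLASS_NEGATIVE, CLASS_CIS_ISOLATED, CLASS_CIS_OTHER, CLASS_TRANS = 0, 1, 2, 3
CLASS_NAMES = {0: "negative", 1: "cis_isolated", 2: "cis_other", 3: "trans"}


@dataclass
class SimConfig:
    """Study-design parameters of the simulation."""

    n: int = 29
    p: int = 1304
    n_chrom: int = 20
    switch_prob: float = 0.05
    q: int = 150
    r: int = 3
    mu: float = 0.15  # signal mean for the hotspots pattern (and trans pairs)
    mu_cis: float = 0.6
    mu_trans: float = 0.15
    lambda_sd: float = 0.001
    sigma_total: tuple = (0.1, 0.1, 0.1)
    sigma_shared: float = 0.0
    pattern: str = "cis_trans"
    hotspot_sizes: tuple = (10, 10, 20, 20, 30, 30)
    n_cis: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sigma_total) != self.r:
            raise ValueError("sigma_total must have one entry per condition")
        if any(s < 0 for s in self.sigma_total) or self.sigma_shared < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.sigma_shared > min(self.sigma_total) + 1e-12:
            raise ValueError("sigma_shared cannot exceed any total noise sd")
        if not 0.0 <= self.switch_prob <= 0.5:
            raise ValueError("switch_prob must lie in [0, 0.5]")
        if self.pattern not in ("hotspots", "cis_trans"):
            raise ValueError("pattern must be 'hotspots' or 'cis_trans'")
        needed = int(sum(self.hotspot_sizes))
        if self.pattern == "cis_trans":
            needed += self.n_cis // 2
        if needed > self.q:
            raise ValueError(f"pattern needs at least {needed} responses, q = {self.q} given")

    @classmethod
    def scaled_down(cls, **overrides) -> "SimConfig":
        """A reduced design (p = 300, q = 50) preserving the pattern proportions."""
        base = dict(p=300, q=50, n_chrom=10, hotspot_sizes=(3, 3, 7, 7, 10, 10), n_cis=10)
        base.update(overrides)
        return cls(**base)


@dataclass
class SimTruth:
    """Generating truth: inclusion pattern, effect sizes and pair class labels."""

    gamma_true: np.ndarray  # (q, p) bool
    lam: np.ndarray  # (q, p) effect sizes, nonzero only where gamma_true
    class_labels: np.ndarray  # (q, p) int8, CLASS_* codes
    hotspot_markers: np.ndarray  # marker column indices of the hotspots
    hotspot_sizes: tuple
    cis_pairs: list  # list of (k, j) cis pairs
    sigma_total: tuple = ()
    sigma_shared: float = 0.0


def simulate_ri_genotypes(cfg: SimConfig, rng: np.random.Generator) -> GenotypePanel:
    """Binary RI-panel surrogate: Markov chains along chromosomes, deduped to p markers."""
    n, p, C, theta = cfg.n, cfg.p, cfg.n_chrom, cfg.switch_prob
    per_chrom = int(np.ceil(p / C))
    # oversample: with flip probability theta, adjacent duplicates occur at rate (1-theta)^n
    extra = 1.0 / max(0.05, 1.0 - (1.0 - theta) ** n) if theta > 0 else 1.0
    m0 = max(per_chrom + 2, int(np.ceil(per_chrom * min(extra, 4.0))) + 2)
    blocks, pos = [], []
    state = rng.random((n, C)) < 0.5  # first marker per chromosome
    for c in range(C):
        cols = [state[:, c].copy()]
        for _ in range(m0 - 1):
            flip = rng.random(n) < theta
            cols.append(np.logical_xor(cols[-1], flip))
        blocks.append(np.column_stack(cols))
        pos.extend((f"chr{c + 1}", m) for m in range(m0))
    X = np.concatenate(blocks, axis=1).astype(float)
    ids = [f"{c}_{m:04d}" for c, m in pos]
    panel = GenotypePanel(X, [f"s{i:03d}" for i in range(n)], ids, pos)
    panel, _ = dedupe_markers(panel)
    tries = 0
    while panel.p < p and tries < 50:
        # top up with a fresh chromosome's worth of markers until p unique columns survive
        add = rng.random(n) < 0.5
        cols = [add.copy()]
        for _ in range(2 * (p - panel.p) + 8):
            flip = rng.random(n) < theta
            cols.append(np.logical_xor(cols[-1], flip))
        c_id = C + tries + 1
        Xa = np.column_stack(cols).astype(float)
        pos_a = [(f"chr{c_id}", m) for m in range(Xa.shape[1])]
        ids_a = [f"{c}_{m:04d}" for c, m in pos_a]
        panel = GenotypePanel(
            np.concatenate([panel.values, Xa], axis=1),
            panel.sample_ids,
            panel.marker_ids + ids_a,
            panel.marker_pos + pos_a,
        )
        panel, _ = dedupe_markers(panel)
        tries += 1
    if panel.p < p:
        raise RuntimeError("could not generate enough unique markers; raise n or switch_prob")
    return GenotypePanel(panel.values[:, :p], panel.sample_ids, panel.marker_ids[:p], panel.marker_pos[:p])


def build_pattern(cfg: SimConfig, panel: GenotypePanel, rng: np.random.Generator) -> SimTruth:
    """Place hotspot and cis markers and assign response blocks.

    Hotspot markers are placed on distinct chromosomes; cis markers prefer
    chromosomes without hotspots, so true signals are not in mutual LD.
    Response blocks of the hotspots are disjoint; cis-isolated responses are
    otherwise unassociated, cis-other responses also belong to a hotspot.
    """
    q, p = cfg.q, panel.p
    sizes = cfg.hotspot_sizes
    n_trans_resp = int(sum(sizes))
    n_cis = cfg.n_cis if cfg.pattern == "cis_trans" else 0
    n_iso = n_cis // 2
    if n_trans_resp + n_iso > q:
        raise ValueError(
            f"pattern needs at least {n_trans_resp + n_iso} responses, q = {q} given"
        )
    chroms = [c for c, _ in panel.marker_pos] if panel.marker_pos else ["chr1"] * p
    by_chrom: dict[str, list[int]] = {}
    for j, c in enumerate(chroms):
        by_chrom.setdefault(c, []).append(j)
    chrom_names = list(by_chrom)
    if len(chrom_names) >= len(sizes):
        hs_chroms = list(rng.choice(len(chrom_names), size=len(sizes), replace=False))
    else:
        hs_chroms = list(rng.integers(0, len(chrom_names), size=len(sizes)))
    hotspot_markers = np.array(
        [by_chrom[chrom_names[c]][rng.integers(len(by_chrom[chrom_names[c]]))] for c in hs_chroms]
    )
    gamma = np.zeros((q, p), dtype=bool)
    labels = np.zeros((q, p), dtype=np.int8)
    start = 0
    blocks = []
    for j, size in zip(hotspot_markers, sizes):
        resp = np.arange(start, start + size)
        gamma[resp, j] = True
        labels[resp, j] = CLASS_TRANS
        blocks.append(resp)
        start += size
    cis_pairs: list[tuple[int, int]] = []
    if n_cis:
        free_chroms = [c for c in range(len(chrom_names)) if c not in hs_chroms]
        pool: list[int] = []
        for c in free_chroms:
            pool.extend(by_chrom[chrom_names[c]])
        if len(pool) < n_cis:
            pool = [j for j in range(p) if j not in set(hotspot_markers)]
        cis_markers = rng.choice(np.array(sorted(set(pool))), size=n_cis, replace=False)
        iso_resp = np.arange(n_trans_resp, n_trans_resp + n_iso)
        other_resp = rng.choice(n_trans_resp, size=n_cis - n_iso, replace=False)
        for k, j in zip(iso_resp, cis_markers[:n_iso]):
            gamma[k, j] = True
            labels[k, j] = CLASS_CIS_ISOLATED
            cis_pairs.append((int(k), int(j)))
        for k, j in zip(other_resp, cis_markers[n_iso:]):
            gamma[k, j] = True
            labels[k, j] = CLASS_CIS_OTHER
            cis_pairs.append((int(k), int(j)))
    return SimTruth(
        gamma_true=gamma,
        lam=np.zeros((q, p)),
        class_labels=labels,
        hotspot_markers=hotspot_markers,
        hotspot_sizes=sizes,
        cis_pairs=cis_pairs,
        sigma_total=tuple(cfg.sigma_total),
        sigma_shared=cfg.sigma_shared,
    )


def simulate_effects(truth: SimTruth, cfg: SimConfig, rng: np.random.Generator) -> SimTruth:
    """Draw effect sizes lambda_kj ~ N(mu_class, lambda_sd^2) on the true pairs."""
    lam = np.zeros_like(truth.lam)
    for cls, mu in (
        (CLASS_TRANS, cfg.mu_trans if cfg.pattern == "cis_trans" else cfg.mu),
        (CLASS_CIS_ISOLATED, cfg.mu_cis),
        (CLASS_CIS_OTHER, cfg.mu_cis),
    ):
        mask = truth.class_labels == cls
        lam[mask] = mu + cfg.lambda_sd * rng.standard_normal(int(mask.sum()))
    return replace(truth, lam=lam)


def simulate_responses(
    X: GenotypePanel, truth: SimTruth, cfg: SimConfig, rng: np.random.Generator
) -> ResponsePanel:
    """Generate Y_l = X B + E_l + E_shared per condition and restack per response."""
    n, q, r = cfg.n, cfg.q, cfg.r
    sig2 = np.asarray(cfg.sigma_total, dtype=float) ** 2 - cfg.sigma_shared**2
    if np.any(sig2 < -1e-12):
        raise ValueError("sigma_shared exceeds a total noise sd")
    sig = np.sqrt(np.maximum(sig2, 0.0))
    B = (truth.lam * truth.gamma_true).T  # (p, q)
    XB = X.values @ B
    E_shared = cfg.sigma_shared * rng.standard_normal((n, q))
    stacks = np.empty((q, n, r))
    for ell in range(r):
        Y_ell = XB + sig[ell] * rng.standard_normal((n, q)) + E_shared
        stacks[:, :, ell] = Y_ell.T
    return ResponsePanel(
        stacks,
        [f"y{k:03d}" for k in range(q)],
        [f"cond{ell + 1}" for ell in range(r)],
        list(X.sample_ids),
    )


def simulate_dataset(cfg: SimConfig, seed: int | None = None):
    """Full pipeline: genotypes, pattern, effects, responses.  Returns (X, Y, truth)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    X = simulate_ri_genotypes(cfg, rng)
    truth = build_pattern(cfg, X, rng)
    truth = simulate_effects(truth, cfg, rng)
    Y = simulate_responses(X, truth, cfg, rng)
    return X, Y, truth
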