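"""Reference methods and the simulation evaluation protocol.

Comparators for the multi-condition model:

* **MANOVA** — a Wilks'-lambda test of the r-variate response on one marker
  at a time (the classical 'one-at-a-time' multivariate approach).  For a
  single-degree-of-freedom hypothesis the F transform of Wilks' lambda is
  exact.
* **ST-HESS** — the single-condition special case of the hierarchical model,
  run per condition.
* **iST-HESS** — the intersection rule: a pair is called when its
  single-condition MPPI exceeds the threshold in *every* condition, which is
  equivalent to thresholding the elementwise minimum across conditions.

Evaluation uses ROC curves over all response-marker pairs and, following the
simulation protocol, classification tables and hotspot-size summaries at a
threshold calibrated so the *realized* (ground-truth) false discovery
proportion is at a set level — an evaluation-only device, distinct from the
user-facing Bayesian FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .api import FitResult, fit_mthess
from .data import GenotypePanel, ResponsePanel
from .simulate import (
    CLASS_CIS_ISOLATED,
    CLASS_CIS_OTHER,
    CLASS_TRANS,
    SimConfig,
    SimTruth,
    simulate_dataset,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreMatrix",
    "ClassificationTable",
    "manova_pair_test",
    "manova_scores",
    "run_st_hess",
    "ist_hess_scores",
    "roc_points",
    "roc_auc",
    "true_fdr_threshold",
    "classification_table",
    "hotspot_size_summary",
    "run_benchmark",
]


@dataclass
class ScoreMatrix:
    """q x p association scores with their orientation."""

    values: np.ndarray
    higher_is_stronger: bool = True
    method_name: str = ""

    def oriented(self) -> np.ndarray:
        return self.values if self.higher_is_stronger else -self.values


@dataclass
class ClassificationTable:
    """2 x 4 cross-tabulation of call status against truth classes."""

    counts: np.ndarray  # rows: negative call / positive call; cols: neg, cis_iso, cis_other, trans
    threshold: float | None
    fdr_level: float
    columns: tuple = ("negative", "cis_isolated", "cis_other", "trans")


def manova_pair_test(Y_k: np.ndarray, x_j: np.ndarray) -> float:
    """Wilks'-lambda MANOVA p-value of one r-variate response on one marker.

    With a single regressor the hypothesis SSCP is rank one, so
    ``lambda = 1 - c' T^{-1} c`` with ``c = Yc' x_hat`` and ``T = Yc'Yc``, and
    the F statistic ``F = (1 - lambda)/lambda * (n - r - 1)/r`` on
    (r, n - r - 1) degrees of freedom is exact.
    """
    Y_k = np.asarray(Y_k, dtype=float)
    x = np.asarray(x_j, dtype=float)
    n, r = Y_k.shape
    if n <= r + 2:
        raise ValueError("need n > r + 2 for the MANOVA F test")
    xc = x - x.mean()
    nx = np.linalg.norm(xc)
    if nx == 0:
        raise ValueError("constant marker: MANOVA test undefined")
    Yc = Y_k - Y_k.mean(axis=0)
    c = Yc.T @ (xc / nx)
    T = Yc.T @ Yc
    lam = float(1.0 - c @ np.linalg.solve(T, c))
    lam = min(max(lam, np.finfo(float).tiny), 1.0)
    F = (1.0 - lam) / lam * (n - r - 1) / r
    return float(stats.f.sf(F, r, n - r - 1))


def manova_scores(X: GenotypePanel | np.ndarray, Y: ResponsePanel | np.ndarray) -> ScoreMatrix:
    """Vectorized MANOVA over all pairs; scores are -log10 p-values."""
    Xv = getattr(X, "values", X)
    stacks = getattr(Y, "stacks", Y)
    n, p = Xv.shape
    q, _, r = stacks.shape
    Xc = Xv - Xv.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    ok = norms > 0
    Xh = np.zeros_like(Xc)
    Xh[:, ok] = Xc[:, ok] / norms[ok]
    Yc = stacks - stacks.mean(axis=1, keepdims=True)
    T = np.einsum("kil,kim->klm", Yc, Yc)  # (q, r, r)
    Tinv = np.linalg.inv(T)
    C = np.einsum("kil,ij->kjl", Yc, Xh)  # (q, p, r)
    lam = 1.0 - np.einsum("kjl,klm,kjm->kj", C, Tinv, C)
    lam = np.clip(lam, np.finfo(float).tiny, 1.0)
    F = (1.0 - lam) / lam * (n - r - 1) / r
    pvals = stats.f.sf(F, r, n - r - 1)
    pvals[:, ~ok] = 1.0
    scores = -np.log10(np.maximum(pvals, 1e-300))
    return ScoreMatrix(scores, higher_is_stronger=True, method_name="MANOVA")


def run_st_hess(X, Y: ResponsePanel, ell: int, **fit_kwargs) -> ScoreMatrix:
    """Single-condition fit (the model specializes automatically at r = 1)."""
    sub = Y.single_condition(ell)
    res = fit_mthess(X, sub, **fit_kwargs)
    return ScoreMatrix(res.mppi, True, f"ST-HESS[{Y.condition_ids[ell]}]")


def ist_hess_scores(per_tissue: list) -> ScoreMatrix:
    """Intersection rule: elementwise minimum of the per-condition MPPI matrices."""
    mats = [m.values if isinstance(m, ScoreMatrix) else np.asarray(m) for m in per_tissue]
    if len(mats) < 2:
        raise ValueError("need at least two condition score matrices")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("shape mismatch between condition score matrices")
    return ScoreMatrix(np.minimum.reduce(mats), True, "iST-HESS")


def roc_points(scores: ScoreMatrix, truth: SimTruth) -> tuple[np.ndarray, np.ndarray]:
    """ROC staircase (FPR, TPR) over all pairs, sweeping all score thresholds."""
    y = truth.gamma_true.ravel().astype(int)
    s = scores.oriented().ravel()
    fpr, tpr, _ = roc_curve(y, s)
    return fpr, tpr


def roc_auc(scores: ScoreMatrix, truth: SimTruth) -> float:
    fpr, tpr = roc_points(scores, truth)
    return float(np.trapezoid(tpr, fpr))


def true_fdr_threshold(scores: ScoreMatrix, truth: SimTruth, level: float):
    """Most permissive threshold with realized FDR = FP/(FP+TP) <= level.

    Calling rule is strict (score > threshold); tied scores enter or leave the
    call set together.  Returns None when no threshold attains the level.
    """
    s = scores.oriented().ravel()
    y = truth.gamma_true.ravel()
    if not y.any():
        raise ValueError("truth contains no positives")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    tp = np.cumsum(y[order])
    fp = np.cumsum(~y[order])
    # candidate cuts: positions where the next value is strictly smaller (tie groups intact)
    last_of_group = np.nonzero(np.diff(s_sorted, append=-np.inf) < 0)[0]
    fdr = fp[last_of_group] / np.maximum(tp[last_of_group] + fp[last_of_group], 1)
    passing = last_of_group[fdr <= level]
    if passing.size == 0:
        return None
    cut = passing.max()  # most permissive call set
    # threshold strictly between this group and the next smaller value
    return float(s_sorted[cut])


def _called_mask(scores: ScoreMatrix, threshold) -> np.ndarray:
    if threshold is None:
        return np.zeros_like(scores.values, dtype=bool)
    return scores.oriented() >= threshold


def classification_table(scores: ScoreMatrix, truth: SimTruth, level: float) -> ClassificationTable:
    """Cross-tabulate calls at the true-FDR-calibrated threshold against truth classes."""
    thr = true_fdr_threshold(scores, truth, level)
    called = _called_mask(scores, thr)
    counts = np.zeros((2, 4))
    for col, cls in enumerate((0, CLASS_CIS_ISOLATED, CLASS_CIS_OTHER, CLASS_TRANS)):
        mask = truth.class_labels == cls
        counts[1, col] = np.sum(called & mask)
        counts[0, col] = np.sum(~called & mask)
    return ClassificationTable(counts, thr, level)


def hotspot_size_summary(scores: ScoreMatrix, truth: SimTruth, level: float) -> dict:
    """Mean number of responses called at each true hotspot marker, per true size."""
    thr = true_fdr_threshold(scores, truth, level)
    called = _called_mask(scores, thr)
    sizes: dict[int, list[int]] = {}
    for j, size in zip(truth.hotspot_markers, truth.hotspot_sizes):
        sizes.setdefault(int(size), []).append(int(called[:, j].sum()))
    return {size: float(np.mean(v)) for size, v in sizes.items()}


def run_benchmark(
    sim_cfg: SimConfig,
    replicates: int = 3,
    methods: tuple = ("mt", "ist", "manova"),
    fdr_level: float = 0.10,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> dict:
    """Simulate replicates and evaluate the requested methods on each.

    Returns per-method lists of score matrices, ROC curves, classification
    tables and hotspot summaries, plus the per-replicate ground truths.
    """
    fit_kwargs = dict(fit_kwargs or {})
    out: dict = {m: {"scores": [], "roc": [], "auc": [], "table": [], "hotspots": []} for m in methods}
    out["truths"] = []
    out["fits"] = []
    for rep in range(replicates):
        rep_seed = seed + 1000 * rep
        cfg = SimConfig(**{**sim_cfg.__dict__, "seed": rep_seed})
        X, Y, truth = simulate_dataset(cfg)
        out["truths"].append(truth)
        per_method: dict[str, ScoreMatrix] = {}
        if "mt" in methods:
            res = fit_mthess(X, Y, seed=rep_seed + 17, **fit_kwargs)
            per_method["mt"] = ScoreMatrix(res.mppi, True, "MT-HESS")
            out["fits"].append(res)
        if "ist" in methods:
            singles = [
                run_st_hess(X, Y, ell, seed=rep_seed + 29 + ell, **fit_kwargs)
                for ell in range(Y.r)
            ]
            per_method["ist"] = ist_hess_scores(singles)
        if "manova" in methods:
            per_method["manova"] = manova_scores(X, Y)
        for m, sc in per_method.items():
            out[m]["scores"].append(sc)
            fpr, tpr = roc_points(sc, truth)
            out[m]["roc"].append((fpr, tpr))
            out[m]["auc"].append(roc_auc(sc, truth))
            out[m]["table"].append(classification_table(sc, truth, fdr_level))
            out[m]["hotspots"].append(hotspot_size_summary(sc, truth, fdr_level))
        logger.info("replicate %d/%d done: %s", rep + 1, replicates,
                    {m: round(a["auc"][-1], 3) for m, a in out.items() if isinstance(a, dict) and a.get("auc")})
    return out
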