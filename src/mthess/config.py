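"""Run configuration, validation and the end-to-end analysis orchestrator."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .api import FitResult, fit_mthess
from .data import GenotypePanel, ResponsePanel, read_genotypes, read_responses
from .postprocess import (
    NO_CALLS,
    association_calls,
    bayes_fdr,
    best_model,
    compute_mppi,
    hotspot_table,
    loo_checking_function,
    threshold_for_bfdr,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_run", "mthess_run"]


@dataclass
class RunConfig:
    """Validated settings of an analysis run; every default is echoed to the run summary."""

    genotypes: str = ""
    responses: list = field(default_factory=list)  # one file per condition
    out_dir: str = "mthess_out"
    e_gamma: float = 2.0
    v_gamma: float = 8.0
    c_rho: float = 1.2
    d_rho: float = 1.2
    d: float = 3.0
    h_mode: str = "empirical"  # or "fixed:<value>"
    n_sweeps: int = 15_000
    burn_in: int = 5_000
    n_chains: int = 3
    response_update_fraction: float = 1.0
    move_probs: tuple = (0.35, 0.35, 0.30)
    bfdr_target: float = 0.05
    hotspot_min_count: int = 5
    adequacy: bool = False
    seed: int = 0
    log_level: str = "INFO"
    force: bool = False

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.genotypes).exists():
            raise FileNotFoundError(self.genotypes)
        for f in self.responses:
            if not Path(f).exists():
                raise FileNotFoundError(f)
        if not 0 < self.bfdr_target < 1:
            raise ValueError("bfdr_target must lie in (0, 1)")


def load_run(cfg: RunConfig) -> tuple[GenotypePanel, ResponsePanel]:
    """Load and align all matrices; error on sample-ID mismatch."""
    cfg.validate()
    X = read_genotypes(cfg.genotypes)
    Y = read_responses(cfg.responses, sample_ids=X.sample_ids)
    logger.info("loaded n=%d p=%d q=%d r=%d", X.n, X.p, Y.q, Y.r)
    return X, Y


def mthess_run(cfg: RunConfig) -> FitResult:
    """Full pipeline: load, elicit, sample, post-process, write the output bundle."""
    out = Path(cfg.out_dir)
    if out.exists() and any(out.iterdir()) and not cfg.force:
        raise FileExistsError(f"output directory {out} is not empty (use force to overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    X, Y = load_run(cfg)
    h_mode, h_value = cfg.h_mode, None
    if h_mode.startswith("fixed:"):
        h_mode, h_value = "fixed", float(cfg.h_mode.split(":", 1)[1])
    add, delete, swap = cfg.move_probs
    res = fit_mthess(
        X, Y,
        e_gamma=cfg.e_gamma, v_gamma=cfg.v_gamma,
        n_sweeps=cfg.n_sweeps, burn_in=cfg.burn_in, n_chains=cfg.n_chains,
        seed=cfg.seed, h_mode=h_mode, h_value=h_value, d=cfg.d,
        c_rho=cfg.c_rho, d_rho=cfg.d_rho,
        sampler_overrides={
            "response_update_fraction": cfg.response_update_fraction,
            "move_probabilities": {"add": add, "delete": delete, "swap": swap},
        },
    )
    mppi = res.mppi
    pd.DataFrame(mppi, index=Y.response_ids, columns=X.marker_ids).to_csv(out / "mppi.tsv", sep="\t")
    thr = threshold_for_bfdr(mppi, cfg.bfdr_target)
    eff_thr = 1.0 if thr is NO_CALLS else thr
    calls = association_calls(mppi, eff_thr, Y.response_ids, X.marker_ids)
    calls.to_csv(out / "calls.tsv", sep="\t", index=False)
    hotspots = hotspot_table(calls)
    hotspots.to_csv(out / "hotspots.tsv", sep="\t", index=False)
    if cfg.adequacy:
        rows = []
        rng = np.random.default_rng(cfg.seed + 99)
        for k in range(Y.q):
            bm = best_model(res.trace, k, res.engine, res.hp)
            score, _ = loo_checking_function(X.values, Y.stacks[k], bm, res.trace, res.hp, k, rng)
            rows.append({"response_id": Y.response_ids[k], "adequacy": score,
                         "best_model": ",".join(X.marker_ids[j] for j in bm)})
        pd.DataFrame(rows).to_csv(out / "adequacy.tsv", sep="\t", index=False)
    summary = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "n": X.n, "p": X.p, "q": Y.q, "r": Y.r,
        "bfdr_threshold": None if thr is NO_CALLS else thr,
        "bfdr_at_threshold": None if thr is NO_CALLS else bayes_fdr(mppi, thr),
        "n_calls": int(calls["called"].sum()),
        "hyperparams": {
            "a_g": res.hp.a_g, "b_g": res.hp.b_g,
            "a_omega": res.hp.a_omega.tolist(), "b_omega": res.hp.b_omega.tolist(),
            "h": res.hp.h.tolist(),
        },
        "acceptance_stats": {k: list(v) for k, v in res.trace.acceptance_stats.items()},
        "temperatures": res.trace.temperatures.tolist(),
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("wrote outputs to %s (threshold=%s, calls=%d)", out, thr, summary["n_calls"])
    return res
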