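# mthess

Bayesian hierarchical sparse regression for simultaneous multi-condition
association mapping — detecting which genetic markers affect which molecular
responses (e.g. gene expression) when every response is measured under several
conditions (tissues, treatments) on the same samples.

## The problem and the model

Given an `n x p` matrix of binary markers and `q` responses, each observed as
an `n x r` matrix (one column per condition), the package fits, for every
response `k`, the sparse multivariate regression

    Y_k = 1 alpha_k' + X_{gamma_k} B_k + E_k,    rows of E_k ~ N_r(0, Sigma_k)

where `gamma_k` selects a common subset of markers across all `r` conditions
(condition-specific effect sizes stay free), and `Sigma_k` is an unstructured
`r x r` error covariance. Three hierarchical devices share information:

- a matrix-variate **g-prior** on `B_k` whose shrinkage factor `g` is common
  to all responses, so many weak, parallel signals can borrow strength;
- a decomposed selection prior `P(gamma_kj = 1) = omega_k rho_j`, where
  `omega_k` is a per-response sparsity level and `rho_j` a per-marker
  **hotspot propensity** shared across responses — a marker that affects many
  responses gets a large `rho_j`, which in turn makes its other associations
  easier to find;
- conjugate integration of `B_k`, `alpha_k`, `Sigma_k`, so the sampler only
  explores `(Gamma, omega, rho, g)` with a closed-form marginal likelihood.

Posterior exploration uses an evolutionary Monte Carlo sampler: three tempered
chains with local add/delete/swap moves, genetic crossover of inclusion rows
between chains, temperature exchange, and a per-response block swap that moves
`(gamma_k, omega_k)` pairs down the ladder. The headline output is the matrix
of marginal posterior probabilities of inclusion (MPPIs), one per
(response, marker) pair, thresholded by Bayesian FDR.

Full model and design details: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a small multi-condition dataset with a known hotspot and fit it:

```python
import numpy as np
from mthess.api import fit_mthess
from mthess.simulate import SimConfig, simulate_dataset

cfg = SimConfig(n=29, p=60, q=12, r=3, n_chrom=4, pattern="hotspots",
                hotspot_sizes=(6,), mu=0.4, sigma_total=(0.1, 0.1, 0.1),
                seed=7)
X, Y, truth = simulate_dataset(cfg)
fit = fit_mthess(X, Y, n_sweeps=4000, burn_in=1200, seed=0)

true_k, true_j = np.nonzero(truth.gamma_true)
print("true pairs:   ", sorted(zip(true_k.tolist(), true_j.tolist())))
print("their MPPIs:  ", np.round(fit.mppi[true_k, true_j], 3))
print("max null MPPI:", round(float(fit.mppi[~truth.gamma_true].max()), 3))
print("E[log g]:     ", round(float(np.mean(np.log(fit.trace.g_samples))), 2))
```

Output (exact numbers are seed-reproducible):

```
true pairs:    [(0, 58), (1, 58), (2, 58), (3, 58), (4, 58), (5, 58)]
their MPPIs:   [1. 1. 1. 1. 1. 1.]
max null MPPI: 0.506
E[log g]:      3.79
```

All six responses attached to the hotspot marker are recovered with MPPI 1.
One null pair reaches MPPI 0.51 — a marker correlated with the hotspot
marker (r = 0.31) that occasionally substitutes for it at n = 29; the
remaining null pairs sit at 0.2 or below. Calls at a target Bayesian FDR
come from `mthess.postprocess.threshold_for_bfdr(fit.mppi.ravel(), 0.05)`.

The same analysis runs from the command line on TSV files:

```bash
mthess-sim --pattern cis_trans --p 300 --q 50 --out data/
mthess-run --genotypes data/genotypes.tsv \
           --responses data/responses_cond1.tsv,data/responses_cond2.tsv,data/responses_cond3.tsv \
           --sweeps 6000 --burnin 1800 --out results/run
```

which writes the MPPI matrix, bFDR calls, posterior hyperparameter summaries
and a JSON run report.

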