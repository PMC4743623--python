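# Methods

This note records the statistical model implemented by `mthess`, the default
parameter choices and their rationale, the simulation generator, the numerical
decisions made in the implementation, and known limitations.

## 1. Model

Data are `q` molecular responses (e.g. expression traits) measured on the same
`n` samples under `r` conditions (tissues), and a common `n x p` matrix of
binary genetic markers. For response `k`, stack the condition measurements as
an `n x r` matrix `Y_k`. The model for each response is a sparse multivariate
regression shared across conditions:

    Y_k = 1 alpha_k' + X_{gamma_k} B_k + E_k,      vec-rows of E_k ~ N_r(0, Sigma_k)

- `gamma_k` is a binary inclusion row over the `p` markers: a marker either
  affects response `k` in **all** conditions or in none. Condition-specific
  effect *sizes* are free (columns of `B_k`), only the selection is shared.
- `Sigma_k` is an unstructured `r x r` error covariance, so conditions may be
  correlated within a response.

### Priors

- `B_k | Sigma_k, g ~ MN(0, g (X'X)^{-1}, Sigma_k)` — a matrix-variate
  g-prior. The shrinkage factor `g` is **shared by all responses**, which is
  what lets many weak, parallel signals (hotspots) borrow strength.
- `Sigma_k ~ IW(delta; h_k I_r)` with `delta = 3` (the smallest value giving a
  finite prior mean `h_k I / (delta - 2)`), and `h_k` set empirically per
  response (Section 3).
- Intercepts `alpha_k` get a flat prior; they are integrated out exactly by
  centering `Y_k` and `X` by their column means (this loses one effective
  observation: all sample-size terms below use `n - 1`).
- Selection: `P(gamma_kj = 1) = omega_k rho_j`, with `omega_k ~ Beta(a_k, b_k)`
  (per-response sparsity) and `rho_j ~ Gamma(c, d)` (per-marker hotspot
  propensity), under the constraint `omega_k rho_j <= 1`.
- `g ~ InvGamma(q/2 + q - 1, nq/2)`, which reduces to the Zellner–Siow prior
  `InvGamma(1/2, n/2)` at `q = 1` and keeps the prior mode at `n/3` for all
  `q` (unit-tested for `q = 1..20`).

### Marginal likelihood

With `B_k`, `alpha_k` and `Sigma_k` integrated analytically,

    log p(Y_k | gamma_k, g) = const_k - (r m_k / 2) log(1 + g)
        - ((delta + n + r - 2)/2) log det( h_k I_r + Yc'Yc - (g/(1+g)) Q_k(gamma) )

where `m_k = |gamma_k|`, `Yc`/`Xc` are the centered data and
`Q_k(gamma) = Yc'Xc_g (Xc_g'Xc_g)^{-1} Xc_g'Yc` is the explained
cross-product. The full constant `const_k` (multivariate gamma functions and
the `-½ r log n` term from the intercept integral) is implemented exactly and
validated two independent ways: against a Helmert-transform multivariate-t
oracle for `r = 1`, and against brute-force Monte-Carlo integration over
`(B, Sigma)` for `r = 2` (both in the test suite).

## 2. Posterior computation

The posterior over `(Gamma, omega, rho, g)` is explored with an evolutionary
Monte Carlo (EMC) sampler: `C = 3` chains at temperatures `1 = t_1 < t_2 < t_3`
(fixed geometric ladder with ratio 1.1, i.e. temperatures 1, 1.1, 1.21).
The mild ratio is deliberate: tempering divides the sparsity prior's
per-marker inclusion penalty (about 5-6 log units at p ~ 300) along with the
likelihood, and at ratio 2 the heated chains respond by saturating at the
model-size cap (measured mean row sizes 14.5-14.8 of cap 15) — expensive to
update and useless as exploration partners, since nothing they hold is ever
accepted downward (block-swap acceptance 2%). At ratio 1.1 the chains stay
sparse (mean row sizes about 2 / 3 / 6) while block-swap and crossover
acceptance run at 36% and 42%, so discoveries actually flow to the cold
chain.
Each sweep, per response and chain:

1. a local Metropolis–Hastings move on the inclusion row (add / delete / swap
   of one marker, probabilities 0.35 / 0.35 / 0.30);
2. a genetic crossover that recombines the row between two chains chosen with
   Boltzmann weights (one-point or uniform crossover), with a
   selection-probability correction for detailed balance.

After the response loop: vectorized logit random-walk updates of all
`omega_k` per chain (their conditionals are independent given `rho`),
vectorized log random-walk updates of all `rho_j`, an adjacent-pair
temperature exchange of full chain states, a per-response **block exchange**
that swaps the pair `(gamma_k, omega_k)` between adjacent chains, and a log
random-walk update of the shared `g` against the cold chain. The block
exchange exists because `(gamma_k, omega_k)` is the natural metastable unit:
a spurious row keeps its own `omega_k` high and vice versa, the crossover
move recombines rows only, and the full-state exchange is essentially never
accepted at realistic `q` (the energy gap across all responses dwarfs one
unit), so without it a wrong local mode on one response can survive
arbitrarily long. Swapping one response's block is a standard tempered
Metropolis move on the product space — the blocks are conditionally
independent given `(rho, g)`, so the acceptance ratio only involves the
affected response — and it is unit-tested against exact enumeration with
every other move disabled. Proposal step sizes are Robbins–Monro
adapted during burn-in only, so the recorded portion is a fixed-kernel chain.
A ladder tuner toward a target full-state swap rate is available
(`LadderConfig(tune=True)`) but off by default: the exchange move swaps entire
chain states, and with many responses the energy gap between chains dwarfs one
unit, so no meaningful spacing can reach a 50% swap target — the tuner then
collapses the ladder to near-identical temperatures (measured: 1, 1.01, 1.02)
and silently removes tempering. With the fixed ladder the hot chains stay hot
and the per-row crossover move carries their discoveries to the cold chain.
Only the cold chain is recorded. Model size is capped at
`min(n - 2, 15)` so the design stays full rank.

Correctness surface: on problems small enough to enumerate every model, the
sampler's marginal posterior inclusion probabilities (MPPIs) are required to
match exhaustive enumeration within 0.02 (twenty fixtures in the acceptance
suite); with hyperparameter updates enabled, the `g` posterior and inclusion
probability on a one-marker problem match 1-D quadrature.

### Convergence budget

On the reduced benchmark design (`p = 300, q = 50`), 2,000 sweeps are *not*
enough: chains can stay locked on a spuriously correlated marker for the whole
run, producing overconfident false MPPIs near 1. The packaged benchmarks use
6,000 sweeps (1,800 burn-in) at the reduced scale and treat anything shorter
as a smoke test. A budget ladder against a 20,000-sweep reference run shows
the MPPI matrix is already stable in the mean (mean absolute difference
~0.004 by 8,000 sweeps); the residual run-to-run variability is confined to
pairs of markers in strong mutual LD (correlation 0.85+), where the posterior
concentrates most of the inclusion mass on one member of the pair and finite
runs can resolve the tie either way. That instability does not shrink with
more sweeps — it reflects genuine posterior multimodality at `n = 29`, not an
unconverged sampler. Escape from early spurious modes is driven by the
tempered chains, the crossover move and the per-response block exchange; the
practical symptom of a genuinely unconverged run is a cluster of high-MPPI
calls on markers weakly correlated with a strong true signal.

## 3. Error-variance scales `h_k`

`h_k` anchors the Inverse-Wishart prior for `Sigma_k` and appears in the
marginal likelihood, so it matters. It is set per response as the **median
across conditions** of the residual variance from a forward stepwise
regression of the condition's trait on the markers (at most 5 terms). The
entry test is a partial-F test at level `0.05 / p` (Bonferroni): with
hundreds of markers, an unadjusted 0.05 entry level lets stepwise selection
absorb noise and deflate the variance estimate several-fold, which in turn
makes the sampler grossly overconfident. The Bonferroni level only admits
predictors that survive multiplicity, recovering the sample variance on null
responses (unit-tested) while still removing real signal variance. The level
is exposed as an argument for users who prefer the classical rule.

## 4. Simulation generator

The generator mimics a recombinant-inbred (RI) expression study:

- **Genotypes**: binary markers along `n_chrom` chromosomes simulated as
  two-state Markov chains with switch probability 0.05 between adjacent
  markers (adjacent-marker correlation `1 - 2 * 0.05`, property-tested),
  started from fair coin flips per chromosome; duplicate and complementary
  columns are pruned at generation, mirroring the marker deduplication the
  package applies to real data.
- **Pattern** (`cis_trans`): six hotspot markers with 10/10/20/20/30/30
  associated responses (trans effects), plus 10 cis pairs — 5 on responses
  with no other signal (*cis-isolated*), 5 on responses that also belong to a
  hotspot (*cis-other*). A `hotspots`-only pattern is available.
- **Effects**: association `(k, j)` gets per-condition effect sizes drawn
  `N(mu_class, 0.001^2)`, with `mu = 0.6` for cis and `mu = 0.15` for trans
  effects.
- **Noise**: per condition `l`, residuals are
  `sqrt(sigma_l^2 - sigma_shared^2) * z_kl + sigma_shared * z_k^shared`, so
  `sigma_l` is the total SD and `sigma_shared^2 / (sigma_l sigma_m)` the
  between-condition correlation (both verified in the acceptance suite).

Full-scale defaults are `n = 29, p = 1304, q = 150, r = 3,
sigma = (0.1, 0.1, 0.1)`; the reduced design (`SimConfig.scaled_down()`)
keeps the pattern proportions at `p = 300, q = 50`. The problem sizes used in
the packaged tests and benchmarks are the package's own choices, picked so
the reduced design preserves the full design's structure while remaining
convenient to iterate on.

## 5. Baselines and evaluation

- **MANOVA**: per (response, marker) pair, Wilks' lambda for the one-way
  multivariate test of the marker on the `r` conditions, converted to an
  F statistic via Rao's approximation; scored as `-log10 p`. The
  implementation is vectorized over all pairs and cross-checked per pair
  against `statsmodels`' MANOVA (which serves only as an independent oracle in
  the tests, not as a dependency of the package).
- **iST**: the single-condition model (`r = 1`) fit per condition, combined by
  the intersection rule — a pair's score is the minimum MPPI across
  conditions, which is exactly equivalent to requiring every condition to
  exceed the threshold (property-tested over all thresholds).
- **Evaluation**: ROC curves on the pooled `(k, j)` pairs
  (scikit-learn's `roc_curve`); Bayesian FDR of a call set
  `{MPPI > c}` as the mean of `1 - MPPI` over the set; *true-FDR*
  thresholding, an evaluation-only calibration that uses the simulation truth
  to pick the most permissive score threshold whose realized false-discovery
  proportion stays at the target (tie groups are atomic; note the realized
  FDR is not monotone in the prefix, so the search must scan all prefixes).
- **Model adequacy**: leave-one-out posterior-predictive checks. For each
  held-out sample the predictive mean and SD under the best model are formed
  by integrating `g` on a log grid over its sampled range and drawing
  `(Sigma, B, alpha)` from their conjugate conditionals; the adequacy score is
  the sum of squared standardized prediction errors. Smaller is better; the
  acceptance suite requires the true model to beat a model missing a true
  predictor in at least 80% of paired replicates.

## 6. Numerical choices

- All likelihood evaluations run through an engine that precomputes `Xc'Xc`,
  `Xc'Y_k`, `Y_k'Y_k` once. The explained cross-product `Q_k(gamma)` is
  **independent of g**, so it is cached per (response, model) and survives `g`
  updates; model sizes 1 and 2 use closed forms, larger models a Cholesky
  solve (LAPACK `dpotrf`/`dtrtrs`). Determinants for `r <= 3` are expanded in
  scalar arithmetic.
- Singular designs (duplicate or complementary marker columns inside a model)
  are rejected by a relative pivot threshold of `1e-6` on the Cholesky
  diagonal; exact singularity can otherwise slip through floating-point
  Cholesky with a tiny positive pivot.
- Per-chain tables of `log w`, `log(1-w)` and inclusion log-odds for
  `w = omega_k rho_j` are cached and refreshed only when `omega` or `rho`
  moves are accepted; all prior terms in MH ratios use closed-form log
  densities with precomputed normalizing constants (constants cancel where
  possible).
- TSV round-trips write floats with `%.17g` and read with pandas'
  `round_trip` parser, making output files bitwise-reproducible inputs.
- One `numpy` `default_rng(seed)` stream drives an entire run (sampler, and
  any derived seeds for sub-fits are drawn as integers below 2^31). Same seed
  implies identical output bytes; the stream itself is not a compatibility
  surface across versions.

## 7. Open design decisions

- The Inverse-Wishart scale uses a single `h_k` for all conditions of a
  response. Under strongly unbalanced noise (e.g. SDs 0.1/0.2/0.4) the median
  across conditions is a compromise; a per-condition scale would leave the
  conjugate structure intact only with a diagonal prior scale matrix, and was
  not pursued.
- The `g` posterior is heavy-tailed (its conditional density decays like
  `g^{-2}` under the `q = 1` prior), so the posterior *mean* of `g` has
  infinite variance. Summaries and tests use `E[log g]`.
- The beta-binomial elicitation defaults (`E[model size] = 2`, variance 8)
  follow the design intent of sparse per-response models; both are exposed.
- Crossover chain selection uses Boltzmann weights on per-row scores; the
  selection-probability correction assumes the second parent is uniform among
  the remaining chains.

## 8. Limitations

- Inclusion is all-conditions-or-none by design; a marker affecting one
  condition only is modeled as included with small effect in the others.
- `p` beyond a few thousand markers is practical only because sweeps cost
  O(active models), but the Q-cache grows with the number of distinct models
  visited; extremely long runs on large `q x p` problems should monitor
  memory.
- The RI genotype surrogate reproduces block LD along chromosomes but not
  real-panel features like segregation distortion or varying marker density.
- MPPI-based bFDR control is a posterior statement: it is honest only insofar
  as the model (and the sampler's convergence) is. The benchmark documents a
  concrete failure mode: unconverged runs produce overconfident false calls
  whose realized FDR exceeds the nominal bFDR.
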