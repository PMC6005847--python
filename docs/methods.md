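# Methods

## Model

`neuroergm` models a binary undirected graph `y` on a fixed node set as an
exponential-family distribution P(Y = y) = exp(theta' g(y)) / c(theta).
The statistic vector `g` is assembled from four term families:

* **edges** — the edge count. Acts as the density intercept; including it
  lets graphs with different natural densities be compared within one
  model instead of being thresholded to a common density.
* **nodecov(attr)** — sum over edges of the endpoint values of a
  quantitative node attribute. Used with the structural covariates
  (degree, clustering coefficient, local efficiency of a companion
  structural network) so that functional-connectivity effects are
  estimated net of the structural substrate.
* **nodemix(attr)** — one edge count per unordered level pair of a
  categorical attribute (module or resting-state-network labels),
  capturing within- and between-module connectivity the way seed-based
  analyses do, but inside the joint model.
* **gwesp(decay)** — geometrically weighted edgewise shared partners,
  `e^tau * sum_{i>=1} [1 - (1 - e^-tau)^i] EP_i(y)`, with `EP_i` the number
  of edges whose endpoints have exactly `i` common neighbors. This is the
  standard declining-weight transitivity statistic; the decay `tau >= 0`
  is held fixed (no curved estimation). A plain triangle count is not
  offered because it is the textbook route to model degeneracy.

Change statistics `delta_ij = g(y + ij) - g(y - ij)` are computed
incrementally in O(local neighborhood) per dyad; the test suite asserts
bit-level agreement with the brute-force toggle difference on exhaustively
sampled small graphs. For GWESP, adding dyad (i, j) contributes
`e^tau (1 - (1-e^-tau)^{c_ij})` for the new edge (with `c_ij` the current
common-neighbor count) plus `(1-e^-tau)^{esp(i,k)} + (1-e^-tau)^{esp(j,k)}`
for every common neighbor `k` whose two flanking edges each gain a shared
partner.

### Rank conventions

When `edges` and a full `nodemix` block are both present the design is
rank deficient, so by default the first between-level cell in level order
is dropped as the reference cell (configurable via `include`/`exclude`).

### Degenerate node metrics

Nodes with degree < 2 receive clustering coefficient and local efficiency
0. Local efficiency is the mean inverse shortest-path length within the
neighbor-induced subgraph; unreachable neighbor pairs contribute 0. Sparse
5–7% density graphs contain many such nodes; if a structural covariate is
consequently constant, the fit aborts with a rank-deficiency error naming
the column rather than silently dropping it.

## Estimation

**Maximum pseudolikelihood (MPLE).** The conditional log-odds of a dyad is
`theta' delta_ij`, so the pseudolikelihood is maximized by a logistic
regression of observed dyad states on change statistics (statsmodels
`Logit`). For dyad-independent models (edges/nodecov/nodemix) this IS the
maximum likelihood estimator, which the tests verify against exact
enumeration. Separation and rank deficiency raise diagnostic errors.

**Sampling.** A Metropolis chain toggles one dyad per step. The default
proposal mixes, with probability 0.5 each, a uniform random dyad and a
tie/no-tie (TNT) proposal that picks an existing tie half the time —
important on sparse graphs, where uniform proposals rarely visit ties. The
TNT Hastings correction is applied exactly; the chain is validated against
the two closed forms available (uniform graph distribution at theta = 0,
independent-Bernoulli occupancy for edges-only models). Defaults: burn-in
`10·D` proposals and thinning interval `D`, where `D` is the number of
free dyads; all controls and the seed live in `SamplerControl`, and
identical controls give bit-identical output.

**Monte Carlo MLE.** Starting from the MPLE (configurable), each outer
iteration draws M networks at the current value `theta_s`, then maximizes
the importance-sampled log-likelihood
`(theta - theta_s)' g_obs - log (1/M) sum_i exp((theta - theta_s)' g(y_i))`
by Newton steps with step-halving, guarded by an effective-sample-size
floor on the importance weights (the inner optimum is found to a scaled
gradient norm of 1e-3). The outer loop stops when the simulated statistic
means match the observed vector within `outer_tol` (default 0.1) simulated
standard deviations — the Monte Carlo version of the MLE moment equation —
and is capped at 20 iterations, returning a flagged (non-converged) result
rather than failing silently. Standard errors are the square roots of the
diagonal of the inverse importance-weighted covariance of sampled
statistics (the Fisher information estimate); t = theta/SE is referred to
the standard normal (the reference distribution is a documented choice),
with significance stars at 0.05/0.01/0.001.

**Degeneracy guard.** If the simulated means drift more than 4 simulated
SDs from the observed statistics (or the chain absorbs at a constant
state), the fit restarts at most twice with doubled burn-in and then
raises `DegeneracyError` carrying the per-statistic table.

**Approximate likelihood ratios.** `approx_loglik_ratio` implements the
importance-sampling estimate of `log c(theta)/c(theta_s)` with a
log-sum-exp shift. The `loglik_ratio` reported on a fit is measured
against the null (uniform) model via reverse importance sampling on the
fit's own draws; it is noisy and intended for model comparison, not
formal testing.

**GWESP decay grid.** `select_gwesp_decay` profiles the fixed decay over a
grid (default 0.05–2.0 in steps of 0.05, i.e. 40 candidates). Because
every candidate GWESP statistic is a deterministic function of the
edgewise shared-partner histogram, one pilot fit at the grid median plus
one reference sample (with per-network ESP histograms recorded) supports
an importance-sampled maximum-likelihood fit at every candidate; the
shared reference cancels the unknown normalizing constant in the
comparison, and candidates whose importance weights collapse are flagged
non-converged. The winner is the converged candidate with the highest
approximated log-likelihood, ties toward the smaller decay — a
quantitative stand-in for the visual MCMC-diagnostics screening such grids
are traditionally read with. The decay is only weakly identified in
sparse, mildly transitive graphs: its profile likelihood is flat, and
selection scatter of ±0.1–0.2 around the generating value is intrinsic
rather than an estimation defect (see the self-consistency test, which
uses a dense, strongly transitive design where the decay is identifiable).

## Temporal models

A transition `y_t -> y_{t+1}` is decomposed into the formation network
`Y+ = y_t ∪ y_{t+1}` and the dissolution network `Y- = y_t ∩ y_{t+1}`, and
recomposed as `y_{t+1} = Y- ∪ (Y+ \ y_t)`; the round trip is exact and
property-tested. Formation coefficients are estimated on the dyads empty
at `t` (ties of `y_t` frozen on), dissolution coefficients on the ties of
`y_t` (all other dyads frozen off); the two likelihoods share no dyads, so
the processes are separable. Panels with T > 2 observations are pooled
with homogeneous coefficients across transitions by default (the paired
per-transition mode is available), each transition entering as an
independent conditional likelihood factor; both conditional MPLE and
conditional MCMC-MLE (toggles restricted to the free dyads) are
implemented, the latter being the default. Positive dissolution
coefficients increase tie survival — `logit P(survive) = theta-' delta` —
which the tests pin down against the Bernoulli closed form. Observation
times are treated as ordered and exchangeable: unequal real-world
inter-scan intervals are not modeled as exposure offsets, a documented
limitation.

## Synthetic data

Patient imaging data are not distributable, so generators emulate the
statistical setting instead:

* **Structural network** — planted-module Bernoulli block model, nine
  module labels by default (the seven canonical resting-state networks
  plus subcortex and thalamus), 148 nodes, within/between tie
  probabilities 0.25/0.04 chosen so the expected density falls in the
  5–7% band observed for tractography-derived graphs; draws are rejected
  until the realized density is in band.
* **Functional network** — simulated from an ERGM whose true coefficients
  include the structural node covariates and a within-module mixing block
  plus GWESP(0.45) (the decay selected for the study data), so a fit that
  omits the structural terms is biased by construction. The density
  intercept starts at a mean-field value and is recalibrated between
  rejection retries until the draw lands in the 10–15% band reported for
  functional graphs; the coefficient vector actually used is returned for
  recovery scoring.
* **Panels** — `simulate_panel` alternates constrained formation and
  dissolution draws; the recovery experiments use formation
  GWESP decay 0.75 and dissolution decay 0.25 (the two fixed decays used
  in the temporal analysis) with coefficients chosen to keep panel
  densities in the 10–15% regime.

What passing these tests shows — and does not. The generators reproduce
binary, sparse, modular graphs with structure-coupled functional ties and
formation/dissolution dynamics; they do not emulate BOLD time series,
partial-correlation network construction, spatial embedding,
scanner/session effects, or heterogeneous lesion pathology. Recovery and
calibration results therefore validate the estimation machinery at study
scale, not the upstream network-construction pipeline.

## Problem sizes and replication counts

Exact-enumeration oracles use all 2^10 five-node graphs (and 2^6
four-node graphs for dyad-independent identities). Null calibration uses
10,000 retained draws on 16 nodes. Recovery experiments use 20 replicates
at n = 50 (static: edges -3.5, GWESP(0.25) 0.4; temporal: 4-network
panels, formation (-4.0, 0.5), dissolution (1.0, 0.3)) scored by ±3 SE
coverage; GOF calibration uses 20 replicates at n = 30 with 150
simulations per report (1,000 is the default for analyses); the decay
self-consistency experiment uses 10 replicates at n = 50 in a
strong-transitivity regime. These sizes were chosen to give stable pass/
fail behavior at desk scale while keeping each experiment's Monte Carlo
error well inside the asserted margins.

## Known limitations

* Only undirected simple binary graphs; no weighted, signed, directed, or
  bipartite variants.
* The GWESP decay is fixed, never estimated as a curved parameter.
* The reverse-importance-sampling log-likelihood ratio is heavy-tailed;
  rankings across very different models should be treated with care.
* p-values use the standard normal reference for theta/SE; no small-sample
  degrees-of-freedom correction is attempted.
* STERGM assumes discrete, exchangeable observation times and homogeneous
  pooled coefficients unless per-transition fitting is requested.
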