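# Methods

This note documents the statistical model behind `symptomnet`, the defaults
and the reasoning behind them, what the synthetic-data generator does and
does not emulate, and the numerical choices that make runs reproducible.

## The Gaussian graphical model and its estimation

The 16 questionnaire items are modelled as nodes of an undirected network
whose edges are partial correlations: with precision matrix Θ (the inverse
of the latent covariance), the weight of edge (i, j) is
`w_ij = −θ_ij / √(θ_ii θ_jj)`, the association between items i and j
conditional on all other items. A zero entry means conditional independence.

Because the items are 4-category ordinal responses with strongly skewed
marginals, the input to estimation is the **Spearman rank correlation
matrix** (average ranks for ties), computed on listwise-complete rows.
Rank correlations of discretized variables can in principle produce an
indefinite matrix; when the smallest eigenvalue is genuinely negative the
matrix is repaired by clipping eigenvalues at 1e-6 and rescaling to unit
diagonal, and the repair is logged with the pre-repair minimum eigenvalue.
Exact singularity (e.g. perfectly collinear toy inputs) is left alone —
the lasso penalty handles it.

The sparse precision estimate maximizes the penalized log-likelihood

    log det Θ − tr(S Θ) − λ Σ_{i≠j} |θ_ij|

over symmetric positive-definite Θ, with the L1 penalty on off-diagonals
only (the graphical lasso). It is solved by the classical blockwise
coordinate-descent algorithm — cycle over nodes, solve each node's lasso
subproblem by coordinate descent, update the working covariance column —
compiled with numba because the bootstrap and permutation machinery refits
the full path tens of thousands of times. Convergence is declared when the
largest working-covariance change in a sweep falls below
`tol × mean |off-diagonal S|` with `tol = 1e-6` and a sweep cap of 10 000.
At λ = 0 on full-rank input the solution is computed directly as the matrix
inverse. The solver is verified in the test suite against two independent
oracles: a dense Cholesky-parameterized Powell optimizer on 3–4-node
problems (objective agreement within 1e-5) and an established library
implementation of the same estimator (entrywise agreement at its tolerance).

**Model selection.** λ runs over a logarithmic grid of 100 values from
λ_max (the largest absolute off-diagonal correlation, above which the
network is empty) down to 0.01·λ_max, solved from the sparse end with warm
starts. Each fit is scored with the extended Bayesian information
criterion

    EBIC(Θ) = −n (log det Θ − tr(S Θ)) + E log n + 4 E γ log p

where E is the number of nonzero upper-triangle entries, p = 16, and
γ = 0.5, the customary default that trades a little sensitivity for
specificity. Ties go to the larger λ (sparser model). Weights below 1e-8
in magnitude are snapped to exact zero so floating-point noise cannot
inflate edge counts. Grid size, ratio, γ and tolerances are all exposed in
`GgmConfig`; simulation-heavy tests use a 20-point grid down to 0.05·λ_max,
which selects essentially the same λ at a quarter of the cost.

## Centrality

Nodal strength, bridge strength (sum of |w| to nodes of the *other* symptom
cluster) and global strength all use absolute weights; a signed
"expected-influence" variant exists behind the `signed=True` flag for
exploration but is not the default path. Standardized profiles use the
population z-score across the 16 nodes. In covariate-adjusted networks the
covariate nodes are excluded from the centrality profile entirely, so they
contribute to neither side of bridge strength.

## Bootstrap stability

- **Edge accuracy:** nonparametric bootstrap (rows resampled with
  replacement, same n), full re-estimation per resample, 2.5/97.5 percentile
  intervals; default 1000 resamples. A resample in which an item has zero
  variance is redrawn (cap 50). Note a boundary effect of percentile
  intervals under selection: an edge estimated as exactly zero in more than
  97.5% of resamples but occasionally large has interval [0, 0] yet a
  positive bootstrap mean, so the interval brackets the bootstrap *median*,
  not necessarily the mean.
- **Case-dropping stability:** for drop proportions 0.1–0.7, subsample
  without replacement (default 500 subsamples per proportion), re-estimate,
  and correlate (Pearson) the subsample centrality vector with the
  full-sample one. The CS-coefficient is the largest drop proportion at
  which ≥ 95% of subsamples correlate ≥ 0.7; subsamples with a constant
  index vector are skipped and logged. A value of 0 means even 10% dropping
  breaks the ranking; 0.7 is the grid ceiling.
- **Difference tests:** for every pair of edges and every pair of node
  strengths, the pair is flagged when the 95% percentile interval of the
  bootstrapped difference excludes 0. All bootstrap machinery shares one
  set of draws per run and is reproducible from (seed, n_boot, config).

## Permutation network comparison

Both group networks are estimated with one shared configuration. Observed
statistics are absolute differences: global strength, each edge weight
(their maximum summarizing overall structure), each node's strength and
bridge strength. Each of n_perm iterations (default 5000) shuffles the
group labels over the pooled rows preserving group sizes and recomputes all
statistics. P-values use the counting rule `P = K/n_perm` with
`K = #{|null| ≥ |observed|}`: the test is declared two-tailed, so counting
is done on absolute differences even though the rule is sometimes quoted
one-sidedly. The literal count can reach zero, which is logged with a
recommendation of the positively biased but never-zero `(K+1)/(n_perm+1)`
estimator available via `plus_one=True`. Edge p-values are
Benjamini–Hochberg adjusted; centrality p-values are reported unadjusted
with a per-test α = 0.05 convention (noted in the output metadata), since
that matches how such comparisons are conventionally reported. The two
groups are treated as independent samples — the survey waves are anonymous
and unlinked — so no paired variant is offered.

## Covariate control

The control analysis re-runs the identical Spearman → glasso → EBIC chain
with demographic columns added as extra nodes (cluster `"covariate"`), then
forms the **delta network**: entrywise |difference| between the plain
network and the item–item block of the adjusted one. Binary and ordinal
demographics enter through the same Spearman correlation as the items; no
dedicated polyserial treatment is attempted, and that choice is pinned.

## The synthetic-data generator

Responses are drawn from a latent multivariate normal whose precision
matrix encodes a known network: within-cluster pairs receive nonzero
partials at a configurable density (default 0.6 — symptom scales are
densely interconnected), cross-cluster pairs exactly `n_bridge_edges`
nonzero partials (default 3), optionally all attached to one anchor node
for recovery tests. Magnitudes are uniform in `partial_range` (default
0.05–0.30, the range typical of reported symptom networks) and positive,
matching the overwhelmingly positive edges of real symptom data. The
precision matrix is made positive definite by geometric shrinkage of the
off-diagonals (bounded retries; an explicit failure names the scenario if
30 steps do not suffice) and rescaled so the latent covariance has unit
diagonal — a pure relabelling that leaves partial correlations untouched
but makes thresholds comparable across items.

Each latent value is cut into categories 0–3 by per-item thresholds placed
at standard-normal quantiles of the target cumulative category
probabilities (default 0.50/0.30/0.15/0.05 — a plausible right-skewed
profile for a community adolescent sample, chosen as a scenario default,
not estimated from any survey). The vacation group receives a latent mean
shift of −0.3 on every item (lower symptom burden off school); demographics
come from fixed categorical distributions and carry no symptom effect
unless `covariate_effects` is set, so null scenarios are exactly null.
Missingness is completely at random at `missing_rate` (default 0).

What the generator does **not** emulate: within-person correlation between
waves (the real waves are unlinked), item-level differential functioning,
informative missingness, and the particular marginal profile of any real
cohort. Passing recovery and calibration tests therefore demonstrates that
the estimation chain is correct and well-calibrated under its own
assumptions — not that any specific real-data result would replicate.

## Problem sizes used in tests and the acceptance script

Simulation studies are sized for a desk-scale single-CPU run: null
calibration of the permutation test uses 200 repeats at n = 500/group with
200 permutations and the 20-point penalty grid; structure recovery uses 50
repeats at n = 1000 with the default grid on an explicitly sparse truth
(within-block density 0.3, partials 0.1–0.3) — at the dense generator
default the estimator legitimately reports many small extra conditional
associations of the discretized variables, and specificity against the
latent truth plateaus around 0.7 even for continuous Gaussian data, so
sparse-truth recovery is the meaningful benchmark. The acceptance script
runs the full pipeline at n = 1000/group with 1000 permutations, 200
bootstrap resamples and 100 case-dropping subsamples per proportion.

## Known limitations

- Spearman input treats the 0–3 items as ordinal but does not model the
  discretization explicitly; polychoric input is out of scope.
- EBIC-glasso at γ = 0.5 is tuned for sparse truths; on densely connected
  truths it trades specificity for sensitivity (see above).
- The CS-coefficient is reported on the 0.1–0.7 grid only, per its standard
  definition; values are not interpolated.
- Exact replication of any real cohort's numbers requires that cohort's raw
  data; the pipeline's claims are correctness, calibration and recovery on
  data with known ground truth.
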