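# Methods

This note documents the models, numerical choices and limitations behind
`netpsych`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Synthetic questionnaire cohorts

### Item catalog

Seven instruments define 83 directly simulated variables: 45 per-source
verbal-abuse items (15 items × parents/peers/supervisors, 0–8), 9 PHQ-9 and
7 GAD-7 items (0–3), 8 LSAS fear/avoidance sub-scores (sums of 5/3/5/6 items
on 0–3, hence bounds 0–15, 0–9, 0–15, 0–18), 4 SAS sub-scores (sums of
5/8/6/7 items on 1–6, hence 5–30, 8–48, 6–36, 7–42), 4 binary CAGE items and
6 ASRS items (0–4). The SAS sub-domain item counts are not part of the
published summary table and were taken from the instrument's validation
literature; only the bounds depend on them. Derived variables are the three
per-source VAQ totals (severity DAG), the 15 source-averaged VAQ items and
the CAGE total (covariance network), giving the 41-node and 50-node analysis
sets.

### Moment calibration

Each bounded ordinal item is generated as `clip(round(a·Z + b), lo, hi)` of
a standard normal latent `Z`. The mean and SD of this transform are
available in closed form (normal CDF differences at half-integer break
points, clipped tails absorbed into the end cells), so `(a, b)` is solved by
`scipy.optimize.least_squares` over `(log a, b)` from several starts. The
calibration contract is |mean error| ≤ 0.02 and |SD error| ≤ 0.05 on the
*analytic* moments; in practice the solver lands within ~0.003 for all 83
items. A clipped-rounded affine transform (rather than a cumulative-probit
threshold model) is used because only two moments per item are published, and
two parameters suffice to match them.

Binary CAGE items are a boundary case: a 0/1 variable's SD is determined by
its mean, so only the mean is truly free; the published SDs are consistent
with the published means to within 0.011, inside the contract band.

### Per-source verbal-abuse profiles

Only source-averaged item moments plus per-source 15-item *total* moments
(3.2 ± 7.7, 3.3 ± 7.5, 2.6 ± 6.4) are published. Per-source item targets are
obtained by scaling the averaged mean profile so each source's expected total
equals its published total mean, and scaling the SD profile by the source
total SD relative to the mean of the three total SDs. The published total
SDs themselves are *not* reproducible under any correlation structure: the 15
published item SDs sum to ~7.1, so even perfectly correlated items bound the
total SD below 7.7. The generator therefore matches total means exactly (in
expectation) and item-level moments within the contract, and lets the total
SD fall where the latent correlation puts it (≈ 3.3–4.2).

### Correlation structure

Latents follow `z = g·G + f·F_instr + sqrt(1 − g² − f²)·ε` with a general
factor `G` (default loading 0.5) and one factor per instrument group
(default 0.4; the three VAQ sources are separate groups). This produces the
positive manifold typical of symptom batteries — within-instrument latent
correlation 0.41, between-instrument 0.25, attenuated on the observed
ordinal scale — without claiming to estimate the real cohort's joint
distribution, which is unpublished. The loadings are configurable and
documented as modelling choices, not estimates.

What the generator does **not** emulate: the extreme zero-inflation/heavy
tails of real abuse-exposure totals (range up to ~99), demographic
covariates, item-level LSAS/SAS responses, and any dependence structure
beyond one general + one group factor. Tests passing on these cohorts
demonstrate correctness of the *pipeline machinery*, not clinical
conclusions about any real population.

## 2. Linear-Gaussian Bayesian networks

The score is decomposable BIC, higher-is-better: for node `v` with parent
set `S`, `score(v|S) = logLik_OLS − (|S|+2)/2 · ln n`, where the
log-likelihood uses the maximum-likelihood residual variance and the penalty
counts intercept, slopes and variance. Ordinal items are scored as
continuous Gaussians — an approximation inherited from common practice in
questionnaire DAG analysis, and the reason learned structures should be read
as dependence summaries rather than literal causal models.

Search is greedy best-improvement hill-climbing over add/delete/reverse
moves starting from the empty graph, followed by `n_restarts` (default 5)
rounds of `n_perturbations` (default 10) random legal moves applied to the
incumbent optimum and re-climbed; the best structure seen is returned.
Numerical choices: improvements must exceed 1e−9 (prevents cycling on
score-equivalent reversals); equal-score moves resolve to the lexicographically
first (move type, source, target) for reproducibility; local scores are
memoized on the centered Gram matrix, so each candidate costs one Cholesky
solve of the parent block. A candidate parent set whose design is singular
(e.g. a bootstrap resample turned a rare item constant) is skipped as an
illegal move; the public `local_bic` raises a rank-deficiency error instead.
Residual variances below machine tiny are floored to keep log-likelihoods
finite; a zero-variance node in `fit_parameters` yields residual variance 0
with a warning.

BIC score equivalence (Markov-equivalent DAGs score equally, to 1e−8 in the
tests) means single learned orientations are arbitrary within an equivalence
class — which is precisely why the bootstrap direction probabilities exist.

## 3. Bootstrap model averaging

`B` resamples of `n` rows with replacement; one hill-climb per resample with
replicate seeds derived from the master seed. A skeleton pair's *strength*
is the fraction of replicates containing it in either direction; its
*direction probability* is conditional on presence. The averaged network
retains pairs with strength ≥ 0.85 and orients by strict majority (> 0.5).
Three deliberate readings (each flagged because the source procedure is
ambiguous): retention counts skeleton occurrences, not direction-specific
ones; an exact 50/50 orientation raises an error by default, while the
pipeline uses the `drop` policy (a tie fails the strict-majority rule); and
because pairs are thresholded independently, a residual cycle is repaired by
deleting the lowest-strength edge on the cycle (lexicographic tie-break),
with every deletion logged — preserving the strongest evidence.

Default `B` at pipeline scale is 200; the procedure supports the
reference-scale 10,000, and the averaging arithmetic is independent of `B`.

## 4. Intra-individual covariance networks

Features are z-scored with cohort-wide *population* (divide-by-n) moments —
the fixed convention, immaterial at large n but pinned for determinism. The
similarity kernel `w = exp(−(z_i − z_j)²)` maps equal z-scores to weight 1
and is strictly positive, so thresholding is what creates sparsity.
Proportional thresholding keeps exactly `round_half_away(K·N(N−1)/2)` edges
(123 of 1,225 at N = 50, K = 0.10); ties at the cutoff break by lexicographic
(i, j), which also makes retained-edge sets nested across K. Weights are
preserved, not binarized, because all downstream metrics are weighted.

## 5. Graph metrics and null models

* **Clustering**: Onnela per-node coefficient on weights scaled by the
  matrix maximum; degree < 2 scores 0.
* **Path length**: Dijkstra on edge lengths `1/w`; the characteristic path
  length averages over *connected* ordered pairs only — flagged because
  thresholded networks can fragment; a fully disconnected matrix is an
  error.
* **Null model**: degree-preserving double-edge swaps (attempts = 10 ×
  edge count by default) with weights carried on the rewired edges; the
  binary degree sequence and the weight multiset are preserved exactly.
  Whether nulls should instead shuffle weights is unspecified in the source
  procedure; carrying weights is the adopted reading.
* **Small-worldness**: γ = C̄/⟨C̄_null⟩, λ = L/⟨L_null⟩, σ = γ/λ; a null with
  undefined path length is redrawn (capped). `n_nulls = 0` is an identity
  test mode. Default 100 nulls per network: the reference-scale 10,000 per
  participant is supported by configuration but the normalization means have
  converged well before that at the sizes analysed here.
* **Modularity**: weighted Newman Q of Louvain partitions (networkx
  implementation), averaged over seeded randomized runs (default 500; the
  per-participant pipeline stage uses 50).
* **Betweenness**: Brandes on lengths `1/w`, endpoints excluded,
  unnormalized pair counts, fractional splitting over tied shortest paths —
  normalization is immaterial because values are rank-transformed
  (tie-averaged ranks 1..N) per participant before any use.

## 6. Sparsity selection, hubs, correlations

For each grid K, each participant's thresholded network is profiled; K is
admissible when ≥ 95 % of participants satisfy σ > 1, Q > 0.3 and
connectedness ≥ 0.80 simultaneously. The analysis K defaults to the
*smallest* admissible value (the lower bound of the admissible range is the
conventional choice; an override is available). An empty admissible set is
an explicit result, not an exception. At cohort scale the K search may run
on a seeded participant subsample (default 50) — the criteria are
cohort-level fractions, and the per-participant metrics are expensive.

Hubs: `floor(0.12·N)` slots (6 at N = 50) filled by each participant's
highest-ranked nodes; prevalence strictly greater than 0.25 flags a hub.
Both the floor and the strict inequality are taken literally from the hub
rule's definition.

Correlations: Spearman rho (tie-averaged ranks, t-approximation p-values
with n−2 df) between each per-source severity total and the
rank-transformed betweenness of the 35 non-VAQ nodes; VAQ nodes are excluded
by contract (their association with their own totals is auto-regressive) and
their presence is an error, not a silent filter. The Bonferroni threshold is
the exact quotient α/m = 0.05/35 ≈ 0.00143 (sometimes quoted rounded to
0.001). Cubic polynomial fits (`numpy.polyfit`, degree 3) are provided for
severity-vs-centrality trend export.

## 7. Pipeline and reproducibility

Stage seeds derive from the master seed via `numpy.random.SeedSequence`
spawn keys indexed by stage; replicate seeds derive from stage seeds the
same way, so every artifact is a pure function of configuration. Two runs
with identical configuration produce byte-identical CSV artifacts. The
manifest records the package version, every threshold and every derived
seed.

## 8. Problem sizes used in the shipped checks

The shipped acceptance checks run the generator at the full published cohort
size (n = 5,616) and the analytic machinery at deliberately small scale —
B = 200 bootstraps on a 5-node planted chain (n = 2,000), 100 random
3-variable structure-recovery problems against the exhaustive 25-DAG
optimum, 50-seed small-world contrasts with 100 nulls, and 200 null
replicates (n = 500, m = 35) for familywise error control. These sizes are
the package's own test-design choices: they make every stochastic assertion
a sound Monte-Carlo test (bounds set at ≥ 3 standard errors of the quantity
under test wherever a printed tolerance would otherwise be inside one SE).

## Known limitations

* Gaussian BIC on ordinal items is an approximation; heavily zero-inflated
  items weaken both edge detection and orientation.
* The generator's positive-manifold correlation structure is a free
  modelling choice; no published inter-item correlations exist to calibrate
  it, so cross-item analyses on synthetic cohorts characterize the method,
  not the population.
* Learned DAG orientations within a Markov equivalence class carry no causal
  information; only the bootstrap direction probabilities quantify
  orientation stability.
* Characteristic path length excludes unreachable pairs, so severely
  fragmented networks can look artificially "short"; the connectedness
  criterion exists to keep the analysis away from that regime.
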