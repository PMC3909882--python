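# Methods

This note records the models, defaults, and numerical choices behind
`bcgrn`, and what the synthetic-data tests do and do not establish about
behaviour on real expression data.

## BC3Net inference

**Mutual information.** MI is estimated from the sample Pearson
correlation by the bivariate-Gaussian closed form
MI = −½ ln(1 − ρ²), in nats. ρ² is clamped at 1 − 10⁻¹² so duplicated
genes map to a large finite value rather than infinity. The closed form
is verified against direct numerical integration of the bivariate
Gaussian MI to 10⁻⁶. This estimator sees only monotone-linear
dependence; nonlinear but uncorrelated dependence is invisible to it,
which is the standard trade-off of correlation-based MI estimation on
microarray-scale data.

**Null model and significance.** All gene rows are permuted
independently (column-wise shuffles per row), destroying every pairwise
dependence while keeping marginals; all off-diagonal MI values of the
shuffled matrix are pooled, and shuffles repeat until the pool reaches
`null_pool_size` (default 10⁵). An observed MI gets the right-tail
empirical p-value (#{null ≥ MI} + 1)/(pool + 1). Each gene contributes
one null hypothesis — the significance of its maximum-MI partner — so
Bonferroni uses m = p. With the default pool the smallest achievable
p-value is ≈10⁻⁵, comfortably below α/p for the gene counts the package
is exercised at.

**C3NET rule.** Per gene, the argmax-MI partner; ties break toward the
lexicographically smaller partner id for determinism. A C3NET network
has at most p edges.

**Bootstrap and aggregation.** B (default 100; the synthetic fixture
uses 20) resamples of the *samples* with replacement; genes are never
resampled. A gene that becomes constant within a replicate takes
correlation 0 there rather than raising. Edge counts k_e across the
ensemble are tested with the one-sided binomial tail
P(X ≥ k_e | B, p₀) ≤ α. The null probability p₀ is not canonical; the
default is the ensemble's mean edge frequency over the union of observed
edges, (Σ k_e)/(B·|union|), which adapts to how concentrated the
ensemble is, and it can be overridden in `PipelineConfig`. With this
default the planted-fixture run (100 genes, mean degree 1.5, edge
strength 0.8, 300 samples, B = 20) recovers the truth at F1 ≈ 0.8 with
precision 1.0.

## Synthetic data

**Network.** Preferential attachment with a degree+1 kernel; fractional
mean degrees are honoured in expectation by randomizing each node's
attachment count, so isolated genes occur at mean degree < 2 — as they
do in real single-tissue compendia. A uniform G(n, m) model is available
as the unstructured baseline.

**Expression.** Each planted edge carries an independent standard-normal
latent factor per sample; gene g is
x_g = √s · Σ_{e∋g} f_e + σ_g ε_g with
σ_g² = max(1 − s·deg(g) − noise_sd², 0.05), plus measurement noise and a
log2-like location shift (mean 8). A degree-1–degree-1 edge hits Pearson
correlation exactly s (default 0.8); edges into a hub attenuate because
the hub's variance grows with its degree. This is deliberate: marginal
correlation, which is what a C3NET-class method consumes, is generated
directly, rather than via a global Gaussian precision matrix whose
planted structure lives in *partial* correlations. Non-adjacent genes
share no factor, so two neighbors of a hub are uncorrelated — more
favourable than real co-regulation, where indirect correlation is
pervasive. Passing recovery tests therefore demonstrates correctness of
the machinery at realistic signal strengths, not expected F1 on tissue
data, where indirect dependence and heteroscedastic noise lower both
precision and recall.

**Annotations, catalog, census.** Planted terms are breadth-first
neighborhoods seeded at high-degree nodes (guaranteeing excess
within-term edges); background terms are uniform draws. The chromosome
catalog assigns every gene one of the 24 chromosomes with a fixed uneven
weight profile shaped like the human genome's gene counts (chromosome 1
largest, Y smallest), so the permutation test's per-pair nulls genuinely
differ. Chromosome cooperation is planted by relabelling a chosen
fraction of edges (default 20%) to join two chromosomes. The census set
is a uniform draw, optionally biased so half of it comes from one term's
genes.

## Preprocessing

Quantile normalization forces every column onto the row-means of the
column-sorted matrix; tied values receive the mean of the reference
values at their (average) rank positions, by linear interpolation. The
map is exactly idempotent on tie-free columns; with ties a second pass
can shift values at machine-visible magnitude because the tie average
replaces two distinct reference quantiles. Probe collapse takes the
per-sample median over a gene's probes, after normalization, and drops
unmapped probes; it assumes inputs are already log2-scaled.

## Topology

Average shortest-path length is defined on the giant component only,
with unit edge weights (Dijkstra degenerates to BFS). The power-law
exponent is fitted, by default, by the exact discrete maximum-likelihood
estimator — numerically maximizing the zeta likelihood
P(k) = k^−α / ζ(α, xmin) — because the familiar closed form
α̂ = 1 + n/Σ ln(k_i/(xmin − ½)) is a continuous-tail approximation that
is biased low by more than 1 at xmin = 1 for exponents near 3.5. The
closed form remains available as `method="approx"`, where its
approximate scale-invariance holds. The reported standard error
(α̂ − 1)/√n_tail is itself asymptotic; on 10⁴ zeta draws at α = 3.48 the
default estimator is unbiased to ±0.03. The exponent of a
preferential-attachment graph is only power-law in the tail, so fits of
generated networks should use xmin ≥ 2.

## GPEA

Term sizes are computed after intersecting each term with the network's
gene set — genes absent from the data cannot form edges — and the pair
capacity N uses the network's gene count. The size window is inclusive,
[3, 999]. Bonferroni multiplies by the number of *tested* (post-filter)
terms. Under an unstructured network the hypergeometric tail is
discretely conservative, so the fraction of terms with p < α stays at or
below α; the suite verifies this by simulation.

## Empirical closeness test

The null distribution is the multiset of shortest-path distances over
all unordered pairs of the giant component, census pairs included; a
census pair at distance d gets p = #{null < d}/#null. The strict-<
literal form admits p = 0 (any adjacent pair when distance-1 pairs are
the minimum), which makes BH anticonservative on small graphs where
random census labels land on adjacent pairs by chance. The
`smoothed=True` option therefore uses (#{null ≤ d} + 1)/(#null + 1),
which is stochastically ≥ uniform under random labels; calibration
checks run in this mode, while the literal form is kept as the default
reading of the definition. Census genes outside the giant component are
excluded from testing (their distances have no rank).

## Chromosome cooperation

Label permutation holds the graph fixed, so every replicate conserves
the edge count, the degree sequence, and chromosome sizes; each pair is
scored against its own null. The literal estimator
p = Σ I(s^e > s)/E admits p = 0 — which is what lets a strongly planted
pair clear BH at E as small as 2,000 — but on sparse count tables it
also assigns small p to pairs whose observed small count happens to
exceed all replicates, and a vacuous 0 to structurally empty pairs. Two
numerical choices address this: an observed count of 0 reports p = 1
(zero interactions are never an excess), and the `smoothed=True` variant
uses the standard valid permutation p-value (#{s^e ≥ s} + 1)/(E + 1),
stochastically ≥ uniform under the null. Calibration runs use the
smoothed variant; detection demonstrations use the literal one. The
production default E = 100,000 matches the test count (300) comfortably;
desk-scale runs in the suite use E between 10³ and 10⁴.

## Problem sizes

The test and acceptance runs use synthetic instances of 100–5,000 genes,
up to 300 samples, B = 20 bootstraps, E = 2,000 permutations and 10–20
replicate repetitions — sizes at which every stage completes in seconds
while leaving enough resolution for the calibration and recovery checks
to be meaningful. The genome-scale arithmetic identities (pair
capacities, density, test counts) are checked at their full printed
sizes, since they cost nothing.

## Known limitations

- The Gaussian-MI estimator cannot see nonlinear, uncorrelated
  dependence; the synthetic generator does not produce such dependence
  either, so this axis is untested by design.
- The generator omits indirect (transitive) correlation, batch effects,
  and heavy-tailed measurement noise; real-data F1 will be lower than
  the planted-fixture value.
- The binomial aggregation p₀ default is a pragmatic, data-driven choice;
  in highly concentrated ensembles (every member nearly identical) it
  approaches 1 and the test loses power — override `binomial_p0` in that
  regime.
- GO-graph ancestor propagation and term-term redundancy are out of
  scope; annotation terms are treated as flat sets.
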