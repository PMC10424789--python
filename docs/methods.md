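# Methods

This note records the models, conventions and numerical choices behind
`cooccurnet`, and what the synthetic tests do and do not establish.

## Network inference

Associations are plain Pearson correlations between taxon abundance
rows across the samples of one soil × treatment group, thresholded at
|r| ≥ 0.9 by default. Choices and caveats:

- **Absolute vs positive thresholding.** Published co-occurrence studies
  often do not say whether they kept negative correlations. The default
  mode is `absolute` (|r| ≥ t, sign retained on the edge) because that
  is the common reading; `positive_only` is a config switch.
- **No p-value filter.** Only the magnitude threshold is applied; adding
  a significance filter would change node/link counts and is left to the
  caller.
- **Scale.** Counts and relative abundances are accepted and correlated
  as-is. Pearson correlation is invariant to per-taxon affine scaling
  but *not* to compositional closure; compositionality-aware measures
  (SparCC, SPIEC-EASI) are out of scope by design.
- **Zero-variance taxa** are excluded before correlation with a warning
  record rather than propagating NaN. **Isolated taxa** (no retained
  edge) are excluded from the node set, so "total nodes" counts
  connected taxa — a drop in nodes means more disconnected species.

## Modules and node roles

Modules come from Louvain modularity maximisation (seeded; a fully
deterministic greedy agglomerative alternative is available). Detection
runs on the unweighted graph: signed correlation weights would violate
modularity's assumptions, and retained magnitudes all sit near the
threshold. Detected communities are split by connected component (two
components never share a module) and renumbered by decreasing size with
lexicographic tie-breaks, so module ids are reproducible. Exact
reproduction of any particular published partition is not attempted —
the algorithm behind published module tables is generally unstated.

Zi is the z-score of within-module degree using the population standard
deviation over the node's module; when that sd is zero (every member
equally connected) Zi is defined as 0 — no hub signal — rather than
undefined. Pi follows the participation-coefficient formula; a node
with all links in its own module has Pi = 0. Role thresholds are the
conventional Zi = 2.5 and Pi = 0.62 with ≥ on the hub/connector side,
and every non-peripheral node counts as a keystone. Note that under
these criteria connectors are typically rare, so keystone counts are
sensitive to the partition; they are reported but carry no acceptance
claim.

Mean shortest-path length is computed over connected pairs of the
largest connected component (sparse thresholded networks are
practically never connected); the component diameter is reported
alongside, since published "average path distance" rows are sometimes
diameters or other statistics and cannot be identified from a single
number.

## Stability

- **Global efficiency** uses unweighted shortest paths (the formula
  counts edges); disconnected pairs contribute 0; n < 2 gives E = 0.
- **Vulnerability** computes E_i on the reduced (n−1)-node graph with
  its own normalisation — "efficiency after removing node i" is a
  property of the reduced graph. Removing a peripheral node can raise
  efficiency (negative term); the maximum is still taken over all nodes.
- **Robustness** removes round(f·n) uniformly random nodes on an
  f-grid with step 0.0005 and counts survivors: non-removed nodes
  retaining at least one surviving link, divided by the original n
  (the secondary-extinction convention). Each repetition draws one
  random removal order; the first k elements of a random permutation
  are a uniform k-subset, so every grid point sees a uniform removal
  while the curve is non-increasing within each repetition. The sweep
  is computed in closed form per repetition (a node at permutation
  position p with latest-removed neighbour position m survives stage k
  iff min(p, m) ≥ k), making 100 repetitions (the default) cheap even
  for thousands of nodes. The scalar summary is the curve interpolated
  at 50 % removal; treatment effects are reported as control-minus-
  treatment differences of this scalar and *signed* vulnerability
  changes, since published accounts of the direction of such changes
  are not always internally consistent.

## Comparison statistics

- **ANOSIM**: R = (mean between-group rank − mean within-group rank) /
  (M/2) with M = n(n−1)/2, midpoint ranks for ties (identical samples
  give R = 0), label-permutation p with the add-one rule; default 999
  permutations.
- **Mantel**: Pearson r over strictly-lower-triangle entries, one-sided
  (greater) p by jointly permuting rows/columns of the second matrix.
  Function profiles are single category rows, so their sample distances
  are |x_u − x_v|; the community matrix uses Bray–Curtis.
- **Dissimilarity** is computed on edge sets (unordered taxon pairs,
  sign ignored; a sign-sensitive mode exists). The default variant is
  Jaccard on links, 1 − a/(L_A + L_B − a); Sørensen and the
  Whittaker-form βWN (algebraically equal to Jaccard on edge sets) are
  labelled variants. Published dissimilarity tables rarely state their
  exact form — recomputing from published link counts gets within
  ~0.005 of printed values under the Jaccard form but not exactly equal
  — so the variant label is always emitted and no exact-match claim is
  made.
- **Preserved modules**: for every pair of big modules (≥ 5 nodes in
  both networks) the 2×2 membership contingency over the union of the
  two node sets is tested one-sided for over-enrichment (hypergeometric
  upper tail P(X ≥ a), via Fisher's exact test). Bonferroni uses
  m = the number of big-module pairs tested for that network pair —
  "within each network" is ambiguous in the literature, and per-pair
  adjustment matches the contingency tables being per network pair.

## Synthetic communities

The generator emulates the incubation design the pipeline targets: two
soils × four treatment levels (control CK and doses L/M/H spanning two
orders of magnitude) × 15 samples (5 sampling days × 3 replicates,
pooled into one network per group — published designs rarely state the
pooling, and pooled groups are the default here).

The abundance model is a latent Gaussian copula: per sample, one shared
background factor and one factor per planted module; taxon i in module
m has latent z_i = √bg·g + √(ρ−bg)·f_m + √(1−ρ)·ε_i, so within-module
correlation is ρ (default 0.95, safely above the 0.9 threshold) and
between-module correlation bg (default 0.1). Optional extra noise
(noise_sd, default 0.2) rescales the latent so marginals stay standard.
Abundances are exp(μ_i + 0.5·z) with lognormal per-taxon baselines —
nonnegative, right-skewed, and with Pearson correlations directly
controlled, which is exactly what the threshold acts on. The lognormal
transform attenuates latent correlations slightly (Pearson of
exponentiated Gaussians), so realised within-module correlations sit
just above/below 0.9 and roughly half the planted pairs survive the
cutoff — comparable in spirit to real tables where most correlations
fail the threshold.

Treatment is planted as **decorrelation, not abundance scaling**: a
fraction `treatment_effect × severity(level)` of taxa (severity 0, ⅓,
⅔, 1 for CK/L/M/H) have their latent rows redrawn as pure noise,
severing their module membership while preserving marginals. This
reproduces the qualitative signature perturbation studies report —
fewer nodes, links and average degree, lower robustness — and gives a
ground-truth set of broken within-module pairs. Default
treatment_effect is 0.8, chosen so that the low dose already roughly
halves the surviving links, the order of magnitude seen in field-soil
studies.

Function tables couple a seed-chosen subset of the 15 standard
predicted categories (CGD; FSD, RR, Translation; CM, LM, AAM, MCV,
XBM, BOSM, EM, MTP, MOAA, NM, GBM) to the community: a linked category
is coupling·score + (1−coupling)·noise where score is the sample's
coordinate on the first Bray–Curtis principal coordinate. A scalar
category row has line-metric distances, and Bray–Curtis on a
multivariate community is not a line metric, so Mantel r at coupling
1 is high but provably below 1 — tests assert strong, not perfect,
correlation. Unlinked categories are pure noise.

**What a green synthetic test establishes:** that the pipeline recovers
planted correlation blocks, module structure and dose-dependent edge
loss under a lognormal abundance model with exchangeable samples. It
does **not** establish behaviour under compositional closure, count
sparsity/zero inflation, temporal autocorrelation across sampling days,
or uneven sequencing depth — none of which the generator emulates.

## Numerical conventions

- All generators and permutation tests are pure functions of explicit
  seeds; the pipeline re-run with the same config is byte-identical
  (except the wall-clock entry of the manifest).
- Reports round average degree to 3 decimals and percentages to 2;
  full-precision values are always written alongside.
- Degenerate inputs have defined behaviour rather than crashes: empty
  networks give all-zero index records with a warning; zero-variance
  taxa are excluded with a warning; E = 0 makes vulnerability a named
  error; both-empty networks make dissimilarity a named error; an
  all-zero sample makes Bray–Curtis a named error.
- Permutation p-values use the add-one rule and so are never 0; ties in
  the permutation statistic are counted conservatively (≥ observed −
  1e−12).

## Known limitations

- Pearson-on-abundance association ignores compositionality; networks
  from relative abundances can contain spurious negative edges.
- Louvain is a heuristic; only seeded determinism is guaranteed, not a
  global modularity optimum, and node roles inherit partition noise.
- Robustness treats all removals as equally likely (no targeted-attack
  or abundance-weighted removal).
- The vulnerability scan recomputes efficiency per node removal
  (O(n²·(n+m))); fine for thresholded networks of a few hundred nodes,
  slow beyond ~2000.
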