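# Methods

This note documents the statistical procedures implemented in `twinupv`,
the assumptions behind them, the tunable parameters and their defaults,
what the synthetic-data generator does and does not emulate, and the
design choices made where the methodology was genuinely open.

## Discordance indices

For a pair oriented by a reference trait (BMI by default; the co-twin
with the lower value is the *light* reference, ties broken by
lexicographically smaller individual ID and flagged), the discordance of
trait t is d_t = ln x_t(heavy) − ln x_t(light). Expression matrices are
assumed to arrive log2-normalized, so expression discordance is the plain
heavy-minus-light difference with log base 2 recorded in the output; both
bases are configurable because upstream normalizations vary. Discordances
are antisymmetric under orientation flips and invariant to per-trait
rescaling — both are enforced by exact tests.

Missing or nonpositive trait values produce missing cells rather than
errors; a pair is dropped only when more than 20% of its cells are
missing (configurable). Height-adjusted variants divide every mass trait
by height² (FatMI/LeanMI analogues); since co-twin heights nearly cancel
in the log difference, d(m/h²) = d(m) − 2·d(height) exactly, which the
suite asserts as an identity.

## Pair typing

Pairs are clustered on the z-scored (per trait) discordance matrix: a
k-nearest-neighbor graph (Euclidean, k default 20, capped at a third of
the pair count) is converted to a shared-nearest-neighbor graph with
Jaccard edge weights, and communities are found by Louvain modularity
optimization (resolution default 0.8, seeded). A 2-D UMAP embedding is
produced for reporting only; membership is never read off the embedding.

**Structure call.** kNN graphs of pure-noise points are spatially local
and therefore modular; comparing against degree-randomized graphs would
over-call structure. The package instead re-runs the entire
graph-construction + clustering procedure on column-permuted copies of
the matrix (each trait permuted independently across pairs), which is
exchangeable with the observed data when no inter-trait structure exists.
Structure is claimed only when the observed modularity exceeds every null
replicate (default 10–20 replicates); otherwise the cohort is reported as
a single concordant cluster.

**Type assignment** is a function of cluster centroids only. With m_fat
and m_lean the centroid means over fat- and lean-tagged traits and m_abs
the mean absolute centroid, the minimal-m_abs cluster is Concordant;
remaining clusters are TypeB when m_fat > 0 and m_lean ≥ τ_lean, TypeA
when m_fat > 0 and m_lean ≤ 0, Intermediate when 0 < m_lean < τ_lean.
τ_lean defaults to half the cohort standard deviation of lean-trait
discordances. When several clusters satisfy the TypeB condition, the one
with the largest m_fat + m_lean keeps the label and the rest are
relabelled Intermediate — the downstream signature derivation needs a
unique Type-B contrast, and clusters with weaker coordinated overgrowth
are by construction transitional. The heat-map ordering uses row-scaled
values, Euclidean distances and complete-linkage agglomeration.

## Paired moderated differential expression

Within each pair cluster, per-pair heavy−light log differences are
regressed on an intercept plus centered pair-level covariates (age by
default; co-twins share age, so the covariate is pair-level by nature —
with DZ or mismatched data the same pair-level convention applies).
Gene-wise residual variances s²_g (df d) are shrunk toward a pooled prior
by empirical Bayes: a scaled inverse-chi-square prior (d₀, s₀²) is
moment-matched on the log-variance scale, using digamma/trigamma
corrections and a Newton inversion of the trigamma function, and the
posterior variance is (d₀s₀² + d·s²_g)/(d₀ + d). The moderated t is
referred to a t distribution with d + d₀ degrees of freedom; BH
adjustment is applied within cluster. With d₀ forced to 0 the procedure
reduces exactly to the ordinary paired t (asserted to 1e-10), and on a
common dataset the prior estimates and moderated statistics agree with an
independent R implementation of the same shrinkage estimator to float
precision (cross-check in the suite).

## Type-B signature

Candidates are genes with p < α (default 0.001) in the Type-B cluster and
p ≥ α in every other cluster. Candidates are k-means-clustered (k default
2) on their **absolute** per-cluster effect profiles, and the gene
cluster whose centroid maximizes |TypeB effect| / (1 + mean |other
effects|) becomes the signature; directions are recorded separately from
the sign of the Type-B effect. Clustering on magnitudes rather than
signed effects keeps up- and down-regulated Type-B genes together (a
signed 2-means would split them and discard one direction) while still
separating strong Type-B-specific genes from borderline false positives.
An empty candidate set is a warning, not an error.

## Stratification, UPV-B rank, PC attribution

Individuals are k-means-clustered (25 restarts, seeded) on z-scored
signature genes for k = 1..10; the chosen k is the *saturation point* of
the dispersion curve — the smallest k whose relative WSS drop to k+1
falls below 10% (both the threshold and k_max are configurable). Cluster
stability is the mean best-match Jaccard over bootstrap reclusterings
(default 50–100 draws); individuals are ordered by BMI within cluster for
reporting.

The UPV-B rank scores each individual as the median over signature genes
of their cohort rank (1..n, average ranks on ties), with ranks of
down-regulated genes reflected (n+1−rank) so that high always means
heavy-like. Reflection is a package choice (toggleable): without it, a
coherent signature with mixed directions would cancel itself. The score
is exactly invariant under monotone per-gene transformations.

PC attribution runs PCA on centered expression (genes as variables);
per-PC gene contributions are squared loadings, which sum to one per PC
by orthonormality. The per-PC association with a gene set is the mean
contribution of its members; PCs sorted by descending association are cut
at the inflection point, formalized as the maximum of the discrete second
difference of the sorted curve (the selection was done by eye in the
workflows this package systematizes). A flat association curve (e.g. the
gene set is all genes) is reported as uninformative rather than selecting
arbitrarily.

## Preranked enrichment

Genes are sorted by the ranking statistic (descending, ties broken by
gene name). Walking the list, set members add |stat|^w normalized over
members (w default 1; 0 gives the classical Kolmogorov–Smirnov-like
statistic) and non-members subtract 1/(N − n_set); the enrichment score
is the signed maximal deviation, with extremum ties resolved to the
positive side at float tolerance. The null is gene-based: random
same-size subsets (default 4,000, seeded), switched to exhaustive subset
enumeration whenever C(N, n_set) ≤ 500, making small-instance p-values
exact — the suite checks equality against an independent enumeration
oracle. p = (1 + #{same-sign |null| ≥ |ES|}) / (1 + #same-sign nulls),
floored at 1/(n_perm+1) with no multi-level refinement; NES divides ES by
the mean |null ES| of matching sign; BH runs across sets. The default
permutation count is sized so that the attainable p-value floor stays
well below the 0.01 adjusted-significance cutoff after BH across a
typical collection. The leading edge is the set members at or before the
extremum (after, for negative ES); the HDAC signature is the union of
leading edges over positively enriched sets at padj < 0.01, and its
per-individual score is the mean z-scored expression over the set.

## Association statistics

Spearman correlations between expression and trait discordances use the
t-approximation for n > 9 and exact enumeration of the rank-permutation
null for n ≤ 9 (cached per n; only applied to tie-free vectors). With
cluster labels, the per-gene mean of p-values over traits is reported per
cluster (the mean-p summary is kept alongside the correlation matrix
itself). Insulin–BMI coupling is measured by per-group OLS (slope, R²,
slope-test p); "insulin adjusted on BMI" means OLS residuals. Variance
homogeneity uses Bartlett's chi-square or Levene's test with
mean-centered absolute deviations; Bartlett errors on zero-variance
groups (the statistic is undefined), Levene proceeds.

The small-cohort analysis splits pairs at the median of their mean
expression of a designated buffer gene (odd counts put the median pair in
the low half), fits a 1-D Gaussian mixture to |discordance| (1 vs 2
components, shared vs free variances, all compared by BIC), labels pairs
concordant (lower-mean component) or discordant by posterior, and
tabulates proportions per half.

## Mixture morph classification

The EM implementation supports free and equal-spherical covariance
classes (the original 14-class taxonomy of model-based clustering tools
is out of scope), k-means++-style initialization over restarts (default
10), a relative tolerance of 1e-8, and a per-iteration monotonicity
guarantee asserted in tests. BIC = −2·logL + params·ln n. The wild-type
reference is a closed-form single Gaussian over (fat, lean) — the traits
are configurable, 2-D by default — with a 1e-6·trace ridge on degenerate
covariances (flagged). Mutant genotypes are fit with component 1 *fixed*
at the reference (weights and the remaining components free; a full refit
is available behind a flag): "applying the reference model" is
interpreted as pinning it, since only that reading makes the wild-type a
supervised anchor. Separation is called when the fixed-reference mixture
beats the reference-only model by BIC (ΔBIC > 0, threshold configurable);
an EM collapse onto the reference is reported as no separation. Free
components are ordered by total mass to map onto light/heavy/obese morph
labels. On small 1-D instances the EM likelihood weakly dominates every
exhaustively enumerated hard assignment (oracle test), and the attained
likelihood matches R's model-based clustering on shared data.

## Synthetic generator: what it emulates, and what it does not

The generator draws the lighter co-twin's traits from log-normal
baselines with sex-specific shifts, and multiplies by exp(effect + noise)
for the heavier co-twin. Defaults: 40 MZ pairs per group (concordant,
Type-A, Type-B, intermediate) + 40 DZ pairs; fat effect 0.35, lean effect
0.18 (Type-A negative, intermediate half-scale), trait noise s.d. 0.08 —
chosen so the planted overgrowth is of the same order as the ~50% body
mass excess seen in heavy morphs, against a realistic measurement/
biological noise floor. Weight effects are a fat/lean composite floored
at a positive fraction of the fat effect so the planted heavy co-twin is
also the heavier-by-BMI co-twin (orientation label noise stays ~1%);
heights are nearly concordant within MZ pairs (log s.d. 0.01). BMI is
derived as weight/height². DZ pairs carry no group effects and their
discordance noise is scaled to 2× the *marginal* MZ discordance s.d.
(effect spread included), so dizygotic pairs are more discordant for
every trait, as they must be. Insulin is a·BMI + ε per group with ε
solved in closed form from the target R² (0.5 in Type-B, 0.1 elsewhere).

Expression plants 2,000 genes: 60 signature genes (25% down-regulated,
the first being the NNAT-like gene) shifted ±1 log2 unit in heavy Type-B
co-twins and ∓1 in their light co-twins, a half-scale shift shared by
both co-twins of intermediate pairs, and 40 HDAC genes shifted +1 in
heavy Type-B co-twins only, over i.i.d. noise of s.d. 0.25. The
symmetric light-co-twin shift and the shared intermediate shift create
the four population strata (light-like / neutral / mildly heavy-like /
heavy-like) that cohort stratification is designed to detect, while
leaving every paired heavy−light contrast outside Type-B exactly null, so
the specificity filter is unaffected. One root seed fans out to fixed
per-stream child seeds (traits, insulin, expression, mice), so changing
the gene count does not perturb trait draws.

Deliberately not emulated: DNA methylation, genotypes, longitudinal
growth trajectories, batch structure, array-specific intensity
distributions, trait correlations beyond the planted group effects
(traits are conditionally independent given the group), and
missing-data patterns. Passing recovery tests therefore demonstrates
that the machinery is correct and well-calibrated under the planted
model — clean group separation, Gaussian noise — not that real cohorts,
with correlated traits, uneven cluster sizes and technical artifacts,
would separate this cleanly.

## Numerical choices and limitations

- z-scores use population (ddof 0) standard deviations; zero-s.d. columns
  pass through unscaled (or as zeros in row scaling, with a warning).
- BMI orientation ties: lexicographic ID tie-break, flagged.
- Enrichment extremum ties: positive side, at 1e-12 tolerance.
- EM degeneracy: variance floor at 1e-8 of the data variance; degenerate
  restarts are discarded, and only if all restarts degenerate is an error
  raised.
- The saturation rule is a hard 10% threshold on relative WSS drop; very
  gradual dispersion curves can be sensitive to it (the curve itself is
  always returned for inspection).
- The pipeline's cached reruns are content-hashed per stage; a stage that
  re-runs invalidates all downstream stages even when their inputs hash
  identically, because in-memory state may differ.
- Exhaustive-enumeration enrichment p-values are exact only for small
  C(N, n_set); elsewhere p is a seeded Monte-Carlo estimate with floor
  1/(n_perm+1).
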