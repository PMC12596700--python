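# Methods

## Strain-sharing inference

Each species' strain phylogeny is reduced to a matrix of leaf-to-leaf
patristic distances divided by the tree's total branch length. Normalization
makes distances comparable across species with very different tree depths and
bounds every value by 1 (no simple path exceeds the sum of all branches).
Rooting is irrelevant: the patristic distance is a property of the unrooted
tree metric, so rooted and unrooted Newick inputs give identical results.

Without longitudinal samples of the same individual there is no direct way to
calibrate "same strain", so the identity threshold is distributional: the 5th
percentile (linear interpolation between order statistics, the default
convention of scientific computing stacks; a nearest-rank variant is
available) of **all** pairwise distances of that species, pooling primary and
secondary samples. Pooling is deliberate — secondary samples thicken the
distance distribution so that genuinely related strain pairs sit in its
extreme low tail. A pair is an event only when its distance is *strictly
below* the threshold; a species whose distances are all identical therefore
yields a zero threshold and no events, and is flagged with a warning rather
than silently producing self-evident "sharing".

Retention filters guard small denominators: species must be profiled in at
least 5 samples (2 primary); pair sharing rates require at least 5 co-profiled
species; transmissibility requires at least 5 potential events. Potential and
observed events for transmissibility are counted among primary-dataset,
same-group sample pairs by default, so the statistic reads "when two group
members have the species, how often do they carry the same strain"; both the
dataset scope and the within-group restriction are arguments.

Because the threshold is a percentile of the realized distribution, it is
conservative but not error-free: when fewer than 5% of pairs are genuinely
related, the cut admits the closest unrelated pairs as events. This is
inherent to the method, reproduced faithfully, and visible in the synthetic
benchmarks as a small (few percent) between-group false-positive rate.

## Synthetic cohort generator

The generator emulates the study conditions the package targets: `n_groups`
(default 6) social groups of 2–5 individuals, each built around a
mother/father reproductive pair plus progeny; ~60% core species present in
every individual (`core_fraction`, remaining species present with probability
`noncore_prevalence` = 0.6); `n_secondary` (default 40) unrelated context
individuals mirroring samples pooled from other studies.

Pairwise sharing indicators cannot in general be realized as tree leaf
distances (two short legs and one long leg on three leaves violate the
triangle inequality), so sharing is generated as an equivalence relation over
strain labels:

- per (group, species), carriers adopt the group strain with probability
  `q = sqrt(p_within)`, otherwise a private strain;
- a group adopts a region-wide strain for a species with probability
  `s = sqrt(p_between / p_within)`;
- progeny copy their mother's label with probability `p_vertical`.

Marginally, a same-group pair without a vertical link shares with probability
exactly `p_within`, a cross-group pair with exactly `p_between`,
mother–offspring pairs with `p_vertical + (1 − p_vertical)·p_within`, and
siblings are elevated through the shared mother — the ordering observed in
real social cohorts. Per-species overrides (`p_within_per_species`,
`p_vertical_per_species`) produce species that differ in transmissibility.

Trees realize the labels as a star of clusters: leaves of one strain cluster
hang off a common node with pendant lengths on the `shared_divergence` scale
(jittered ×U(0.5, 1.5)); cluster nodes sit at heights on the
`unshared_divergence` scale (×U(0.75, 1.25)). Defaults 0.01 / 0.5 keep the two
scales separated by more than an order of magnitude after jitter.
Normalization by total branch length shrinks both by a common factor, so the
contrast — which is what the percentile threshold consumes — is preserved.
Topology realism is deliberately not attempted: downstream inference consumes
only leaf distances.

What the generator does *not* emulate: marker-alignment noise, within-strain
diversity gradients, multi-sample individuals, linkage between species,
seasonal or dietary effects, and read-level data. Passing tests therefore
demonstrate that the inference machinery recovers seeded transmission
structure under the stated model, not that any particular biological dataset
would behave this way.

Abundance tables are log-normal with a per-(group, species) additive
log-effect of scale `group_effect_scale` (1.0 by default; 0 gives a null
table for calibration experiments), closed to unit sum per sample. GPS points
scatter uniformly (±`gps_jitter_m`, default 150 m) around group centers laid
out on a grid with `territory_spacing_m` = 500 m, expressed both in UTM 39S
meters and back-projected WGS84 degrees. MASH matrices are block-structured
with characteristic distances 0.02/0.10/0.22/0.40 (within-SGB, within-GGB,
within-FGB, across-FGB) plus ±0.005 uniform noise, validated never to straddle
the 0.05/0.15/0.30 cutoffs.

All generators draw from deterministic substreams of one master seed (stream
names hashed into the seed sequence), so any output is reproducible from the
configuration alone.

## Genome cataloging

Quality classes use inclusive boundaries (completeness ≥ 50 / ≥ 90,
contamination ≤ 5). Assignment to an existing catalog takes the nearest
representative per level with inclusive cutoffs (a genome exactly at 0.05
joins the SGB). De novo clustering is average linkage on the full MASH matrix
with flat cuts at 0.05/0.15/0.30; cutting one dendrogram at increasing
heights makes the SGB → GGB → FGB nesting hold by construction. Clustering of
unassigned genomes is global rather than per-family-neighborhood (the
neighborhood decomposition is an optimization, not a different model). Exact
merge-height ties are broken by the linkage implementation's deterministic
merge order; identical inputs always give identical partitions. Majority-rule
taxonomy ties are broken lexicographically and flagged. Representatives
maximize completeness − 3 × contamination, ties again lexicographic. Coreness
is prevalence within the `min(2000, n)` highest-quality genomes of the bin.

## Networks and statistics

Degree is unweighted ("number of connections" — the definition the analysis
reports), with weighted degree as an extra column. Eigenvector centrality is
the principal eigenvector of the full weighted adjacency (symmetric
eigendecomposition, equivalent to converged power iteration), max-normalized;
on disconnected graphs nodes outside the dominant component come out at ~0,
which matches the behavior expected for sparse actors. Betweenness is
computed on the unweighted graph (no weight-to-length mapping is defined for
shared-strain counts), pair-normalized.

Two-group comparisons use the Wilcoxon rank-sum test (exact where scipy
selects it) with effect size r = |Z|/√N from the tie-corrected normal
approximation; k > 2 groups use tie-corrected Kruskal–Wallis with post-hoc
Dunn z-tests (pooled-variance, tie-corrected) adjusted by Benjamini–Hochberg
within the family of pairwise comparisons. All-identical inputs short-circuit
to H = 0, p = 1. Spearman correlations use average ranks with the
t-approximation p-value; zero-variance inputs are flagged as degenerate
rather than returning an arbitrary coefficient.

## Spatial analysis

Projection is transverse Mercator on WGS84 via the Krüger series in the third
flattening, truncated at order n⁶ (sub-millimeter inside a UTM zone), with
standard UTM constants (k₀ = 0.9996, false easting 500 000 m, southern false
northing 10 000 000 m); the inverse uses the dual series plus Newton
iteration on the conformal latitude. Tests hold it to < 1 m against an
independently derived series expansion. Territories are convex hulls of 100%
of a group's projected points (MCP100); areas are reported in hectares
(m²/10⁴, raw m² recoverable). Degenerate hulls (< 3 distinct or collinear
points) get area 0, a flag, and the point mean as centroid; proper polygons
use the area-weighted centroid, not the vertex mean. The
sharing-versus-distance correlation assigns within-group pairs distance 0 and
includes them by default (configurable), pairing each individual pair with
its group-centroid distance.

## Compositional analysis

The 0.001 mean-abundance filter runs first; zeros are then imputed with each
species' minimum nonzero proportion, rows re-closed to unit sum, and CLR
applied with natural logs (row sums 0 to 1e-10). Ordering — filter, impute,
re-close — follows compositional convention. Simpson's index is reported
primarily as 1 − Σp² with Σp² and 1/Σp² as companion columns, since
"Simpson's diversity" is ambiguous across software. Pielou is
Shannon/ln(Observed), undefined at a single species. PCoA is classical
Torgerson scaling (double-centering + eigendecomposition, positive axes
only). PERMANOVA computes pseudo-F from the Gower decomposition
(R² = SS_between/SS_total) with free label permutations (no strata), 999 by
default, p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1), and reports the Ezekiel
adjustment 1 − (1 − R²)(n − 1)/(n − k − 1) alongside the plain R² because
published "adjusted R²" values are not always explicit about which is meant.

## Problem sizes and calibration checks

The validation experiments run at desk scale: clustering oracle equivalence
on 1000 random matrices of up to 8 genomes; betweenness enumeration on graphs
of up to 7 nodes; ground-truth recovery over 20 seeded cohorts of 6 groups /
~20 individuals / 30 species; transmissibility recovery at 40 species with
per-species probabilities U(0.1, 0.9); PERMANOVA type-I calibration over 500
null tables at 199 permutations (target rejection 3–7% at α = 0.05); and a
geography-null experiment over 100 seeds in which sharing is independent of
distance. These sizes keep the whole suite under a minute while leaving each
check statistically meaningful.

## Known limitations

- The percentile threshold inherits the method's false-positive floor (see
  above); threshold-zero species produce no events by design.
- One sample per individual; longitudinal designs are unsupported.
- The generator's sharing model is an equivalence relation; it cannot seed
  intransitive sharing patterns, because no tree metric can realize them.
- PERMANOVA assumes exchangeable samples under the null; group-structured
  covariance (strata) is not implemented.
- The UTM implementation targets in-zone use; far outside the zone the series
  (like all fixed-order series) degrades, and inputs are only warned about,
  not rejected.
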