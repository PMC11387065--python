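# Methods

This note records the statistical conventions, the synthetic-data model
and the numerical choices behind `dietshift`, at the level a maintainer or
reviewer needs to interpret the outputs.

## Data model

The unit of observation is a **herd-level sample**: pooled faecal material
from one herd, yielding read counts over plant taxa. Counts are assumed
already collapsed to taxa (no sequence processing happens here). Samples
carry species, season (winter/spring/summer/autumn), herd id and date.
Seasonal hypothesis tests use summer vs winter only; spring/autumn samples
are retained in tables but excluded by a season filter.

## Table preparation

* **Depth filter.** Samples with fewer than 1000 total reads are removed.
  The threshold is strict (`< 1000`): a sample with exactly 1000 reads is
  kept.
* **Rarefaction** draws each sample down to a common depth (default 1453)
  *without replacement* (multivariate hypergeometric), the standard
  choice for read-count rarefaction: a taxon can never gain reads and
  never appears where it was absent. The draw is seed-reproducible.
* **Functional aggregation** sums member-taxon counts into eight groups
  (coniferous tree, non-coniferous tree, forb, grass, non-grass graminoid,
  shrub, other, undetermined). Unannotated taxa default to undetermined.
  When the undetermined group is excluded, samples are re-rarefied to a
  stated depth so rows stay comparable.

## Diversity and specialization metrics

* **Bray–Curtis**: BC(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) ∈ [0,1]. All-zero rows
  are rejected.
* **Richness**: count of strictly positive entries per sample.
* **Total niche width (TNW)** standardizes richness to a common number of
  sampling units t using incidence frequencies (Y_j = number of units
  containing taxon j; Q_k = number of taxa with Y_j = k). For t ≤ T the
  exact interpolation S(t) = S_obs − Σⱼ C(T−Yⱼ,t)/C(T,t) equals the mean
  richness over all size-t unit subsets (verified against exhaustive
  enumeration). For t > T the Chao2 extrapolation
  S(T+t*) = S_obs + Q̂₀·[1 − (1 − Q₁/(Q₁+T·Q̂₀))^t*] is used with
  Q̂₀ = ((T−1)/T)·Q₁²/(2Q₂), or the bias-corrected ((T−1)/T)·Q₁(Q₁−1)/2
  when Q₂ = 0. When Q₁ = 0 the asymptote is attained and S_obs is
  returned. The default standardization point t = 8 from T = 4 units sits
  exactly at twice the sample size; extrapolation beyond 2T is permitted
  but logged. Only sample-size-based standardization is implemented (no
  coverage-based variant, no Hill-number generalization).
* **Blüthgen d′.** With row shares p_ij and network-wide column shares
  q_j, the raw index is the KL divergence d_i = Σⱼ p_ij ln(p_ij/q_j).
  Normalization treats read weights as *continuous*: d_min = 0 and
  d_max = ln(1/q_min) with q_min the smallest positive column share, so
  d′ = d/d_max clipped to [0,1]. The classical integer-constrained
  normalization (marginal-preserving rewiring) is not implemented; this
  closed-form convention preserves the 0–1 interpretation and the
  orderings used by the hypothesis tests, but absolute d′ values can
  differ from implementations that use the integer algorithm. Networks are
  built from relative read abundances of rarefied counts (not
  presence/absence): rarefaction to equal depth makes rows comparable.
  Herd-level d′ uses all same-season samples as rows and averages per
  species; species-level d′ uses mean relative-abundance profiles.

## Permutation statistics

All permutation p-values use (1 + #{stat_perm ≥ stat_obs})/(1 + n_perm),
so p ≥ 1/(n_perm+1). When n! ≤ 10 000 (n ≤ 7) the permutation set is
enumerated exhaustively and the p-value is the exact orbit proportion.

* **perMANOVA** Gower-centres G = −½·C·D²·C and partitions trace(HG) by
  the sequential (by-terms) design species → season → interaction, with
  pseudo-F = (SS_term/df_term)/(SS_res/df_res) and free whole-row
  permutation. Cumulative design bases are built by SVD (dummy blocks are
  rank-deficient; unpivoted QR is unreliable there). Verified against R
  `vegan::adonis2` to 1e-8 per term.
* **Dispersion** embeds D by principal coordinates keeping imaginary axes;
  squared distance to the group centre is (real part) − (imaginary part),
  floored at 0. The centre is the spatial median by default (computed
  separately in the real and imaginary subspaces, Weiszfeld iteration),
  with centroid as an option; the reference betadisper matches both to
  1e-8 (centroid) / 1e-4 (median, different optimizer). Bias adjustment
  multiplies group-g distances by √(n_g/(n_g−1)). The permutation test
  permutes *model residuals* (distance minus own-group mean) and refits,
  which is noticeably better calibrated than permuting raw distances;
  like the reference implementation the test remains mildly conservative
  in small samples (empirical type-I ≈ 0.04 at 10 samples/group).
* **Mantel**: Pearson correlation over lower triangles, simultaneous
  row/column permutation of one matrix.
* **NMDS** minimizes Kruskal stress-1 by alternating isotonic regression
  of embedded distances on the dissimilarities with SMACOF (Guttman)
  updates; restarts include a principal-coordinate start plus random
  starts, and the recorded stress sequence is non-increasing (iteration
  stops if an update would raise it).

## Resampling and allometric tests

* The balanced design draws 4 samples per species–season cell, 100 times,
  without replacement within a replicate. Turnover is the mean Bray–Curtis
  over all 4×4 summer × winter pairs within species (not
  centroid-to-centroid; a centroid option exists on the profile level via
  species means).
* Hypothesis tests run on per-species–season means of the replicates
  (the "thick line"); per-replicate fits are kept as a descriptive
  envelope. Body mass enters as log₁₀(mass in grams); the base is
  configurable and recorded because slope magnitudes depend on it.
* **ANCOVA** uses sum-to-zero factor coding and Type III sums of squares,
  with the mass covariate centred so the balanced species × season design
  is orthogonal (Type III = Type I there, and the season effect is
  evaluated at the mean mass). Model simplification follows a
  likelihood-ratio chain — drop the interaction if slopes are homogeneous,
  then drop any main effect whose removal is not significantly worse —
  implemented through the *exact F form* of the nested-model likelihood
  ratio: on the ten cell means the χ² approximation is anticonservative
  (empirical interaction type-I ≈ 0.14 instead of 0.05), while the F form
  is exact under Gaussian errors (type-I = 0.05, verified by simulation).
* **Log-response ratios** are ln(summer mean / winter mean) per species,
  computed from seasonal means (herds are unpaired across seasons).

## Movement and habitat

Windows collect an animal's fixes from the 72 h before its sampling time
(inclusive endpoints; a 4 h interval yields 19 fixes). Windows with no
fixes are flagged missing and excluded from spatial analyses rather than
erroring the run. The fix polyline is buffered by 400 m with round
caps/joins (a single fix gives a disc of π·0.4² ≈ 0.5027 km²; a straight
1 km track a 1.3027 km² stadium). Zonal summaries count raster cells by
centre-in-polygon membership — at 30 m cells the stadium's rasterized area
is within 2% of the analytic value, within 0.5% at 5 m — and report mean
elevation, area (km²), habitat richness (distinct cover classes) and
cover proportions. Coordinates are planar metres in a local frame; no
geographic projections.

## Synthetic community generator

The generator produces the statistical structure the analysis assumes,
with effect sizes that are explicit, seedable parameters.

* **Mechanism.** Each species–season has a mean profile over a global
  taxon pool; herd samples are compound multinomial (Dirichlet herd
  profile with total concentration α₀, default 100, then a multinomial of
  1453 reads), so rows sum to the rarefaction depth exactly and
  between-herd dispersion is controlled by one parameter
  (α₀ → ∞ collapses herds onto the species profile).
* **Turnover** follows BC(s) = 0.90 − 0.07·(log₁₀ m_g − 5). The
  cross-season shared profile mass is calibrated *at the count level*: a
  normal approximation of E|x−y| for Dirichlet-multinomial counts is
  inverted (Brent root-finding) so sampling noise — which otherwise
  inflates dissimilarity more for richer, larger species and biases the
  recovered slope toward zero — is already accounted for. Realized
  per-pair means match the target line to ~0.01.
* **Richness** targets 35 + 15·(log₁₀ m_g − 5) taxa per sample, ±7 by
  season (summer − winter = 14). Within-segment abundances decay as
  rank^−0.6 so rare taxa exist (giving non-trivial incidence frequencies
  for the TNW estimator), and segment taxon counts are inflated by the
  exact Dirichlet-multinomial non-detection probability so the *detected*
  richness hits the target (realized values within a few percent).
* **Uniqueness.** Season-specific "commons" taxon pools (Zipf-weighted so
  different species pick overlapping taxa) are shared across species. In
  winter the commons fraction of a species' diet declines with mass
  (0.75 − 0.45·Δlog₁₀ m); in summer it is constant (0.75). Larger species
  therefore hold more exclusive winter diets, producing the size × season
  interaction in both d′ indicators. The defaults reproduce all four
  qualitative sign patterns in ≥ 90% of seeds (measured: 20/20).
* **Null configuration** sets the turnover, richness and commons slopes
  and the season delta to zero, keeping realistic noise; it drives the
  type-I checks of the downstream ANCOVA chain.
* **Movement** is a correlated random walk (wrapped-normal turning,
  gamma step lengths scaled per species/season, larger and summer animals
  stepping farther) on smoothed Gaussian random-field rasters (elevation;
  cover classes from quantile-binned fields at ~500 m patch scale).
  Tracks that would leave the raster raise an error rather than being
  clipped.

**What the generator does not emulate:** phenology and green-wave timing,
spatial autocorrelation between neighbouring herds, taxonomic structure
(taxa are exchangeable labels), collar fix loss, multi-year effects, and
snow or predation layers. Passing tests therefore demonstrate that the
statistical machinery recovers known effects under the assumed sampling
model, not that the field data meet those assumptions.

## Validation conditions and problem sizes

The packaged experiments (`dietshift.evaluation`) use: 500 simulations per
permutation-test null (n = 16–20 samples, 99 permutations each); 20
generator seeds for turnover-slope recovery at the study design (5
species × 2 seasons × 4 samples, 100 replicates, depth 1453); 20 seeds ×
100 replicates for the sign-pattern rate; and 40 null-generator seeds for
the end-to-end ANCOVA type-I check. These sizes give binomial standard
errors of ~0.01 on the type-I rates while keeping a full validation run in
the minutes range on one CPU.

## Known limitations

* d′ uses the continuous normalization (above); comparisons with
  integer-algorithm implementations should be made on orderings, not
  absolute values.
* The dispersion permutation test inherits the small-sample conservatism
  of its reference implementation.
* TNW extrapolation is only as good as Chao2's lower-bound behaviour when
  detection heterogeneity is extreme.
* The movement generator's step scale is a phenomenological allometry
  (∝ mass^0.25), not a fitted movement model.
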