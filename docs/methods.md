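# Methods

This note documents the statistical procedures the package implements, the
design decisions taken where the methodology is genuinely open, the synthetic
cohort generator and what it does and does not emulate, and the numerical
conventions that make runs reproducible.

## 1. Symptom matrix and standardization

The clustering input is a subjects × 16 matrix of ordinal QIDS-SR item
scores (integers 0–3).  Each item is standardized to mean 0, standard
deviation 1 so that all items carry equal weight in the Euclidean geometry.
The sample (n−1) standard deviation is used — the default of mainstream
statistical environments; since standardization rescales every column by a
common convention, the choice of n vs. n−1 is immaterial to the cluster
geometry.  Zero-variance items cannot be standardized and are either dropped
with a warning (default) or raise, per `zero_variance_policy`.

Endorsement profiles summarise a subtype as the percentage of its members
scoring at or above a threshold per item.  The threshold defaults to 1 — the
weakest "symptom present" reading of a QIDS item — and is configurable
(`threshold` ∈ {1, 2, 3}).

## 2. Clustering

**Maximin initialization.**  The first center is a data point drawn
uniformly at random; each subsequent center is the data point maximizing the
minimum Euclidean distance to the centers already chosen.  Ties break toward
the lowest subject index.  A `refine_first=True` variant replaces the random
first center by one assign/update pass (with a single center, the data
mean) before the maximin sweep; the default is plain maximin because it
keeps the first center reproducible as a function of the seed alone.
Deliberately *not* implemented: k-means++ probabilistic seeding and
accelerated/mini-batch variants.

**Lloyd iterations.**  Assign to the nearest centroid, recompute means,
until the maximum centroid displacement falls below `tol = 1e-6` or
`max_iter = 100`.  The within-cluster sum of squares is non-increasing
across iterations (recorded in `wss_history` and asserted in tests).  A
cluster emptied during iteration is reseeded at the point farthest from its
assigned centroid — deterministic given the current state.

**Ward tree.**  Validity indices are evaluated on the nested partitions of
an agglomerative Ward tree in the ward.D2 convention (Euclidean, not
squared, distances fed to the Lance–Williams update), via
`scipy.cluster.hierarchy.linkage(method="ward")`.  Cuts use `cut_tree`,
which cuts after n−k merges and therefore returns exactly k clusters even
when merge heights tie (e.g. duplicated subjects in noiseless cohorts).

## 3. Choosing the number of clusters

Twelve validity indices are computed on the Ward partitions over the
requested k range (extended internally by one k on each side for the
difference-based rules):

| index | definition | best-k rule |
|---|---|---|
| Calinski–Harabasz | (tr B/(k−1))/(tr W/(n−k)) | max |
| Scott | n·ln(det T/det W) | max successive difference |
| Friedman | tr(W⁻¹B) | max successive difference |
| Marriot | k²·det W | max second difference |
| TraceW | tr W | max second difference |
| Rubin | det T/det W | min second difference |
| Ball | tr W/k | max successive difference (decreasing) |
| Hartigan | (tr W_k/tr W_{k+1} − 1)(n−k−1) | max successive difference (decreasing) |
| KL | \|DIFF_k/DIFF_{k+1}\|, DIFF_k = (k−1)^{2/p} tr W_{k−1} − k^{2/p} tr W_k | max |
| C-index | (S_w − S_min)/(S_max − S_min) | min |
| silhouette | mean silhouette width | max |
| Davies–Bouldin | mean worst within/between ratio | min |

T, W, B are the total, pooled-within and between scatter matrices
(T = W + B elementwise, asserted to 1e-8 on every call).  Scott and Friedman
use the max-difference-between-successive-k rule, their standard semantics;
each index's rule is stored with the index rather than hard-coded, and the
battery roster is a configurable argument.

Each index nominates a best k; the k with most nominations is chosen, ties
breaking toward the smaller (more parsimonious) k.  Degenerate values —
singular within-scatter making determinant/ratio indices non-finite, which
is the rule rather than the exception on noiseless planted cohorts — are
flagged, and an index with fewer than two finite values over the range (or a
completely flat series) casts no vote.  The report records votes, tie
breaks, whether the winner had a strict majority, and the per-index values.

**Permutation test.**  The chosen k's index (Scott or Friedman by default)
is compared with an empirical null obtained by independently permuting each
column of the scaled data — destroying the joint structure while preserving
every item's marginal — then re-clustering with the same clusterer at the
same k and recomputing the index.  p = (1 + #{null at least as extreme}) /
(n_perm + 1) (add-one rule, so p is never 0; tail oriented by the index's
direction; degenerate permutations count as extreme, and more than 10%
degenerate aborts with diagnostics).  Under this scheme a structure-free
cohort is exchangeable with its column permutations, so the p-value is
uniform; the acceptance suite verifies the 5% rejection rate over 200
simulated null cohorts.

## 4. Stability analysis

A training partition (70% of subjects) is fixed once per analysis.  Each
replicate draws `subsample_size` subjects (default 100) without replacement
from it, re-runs maximin k-means on the subsample, fits a linear
discriminant classifier to the subsample's cluster labels, and assigns every
subject outside the subsample with it.  The completed labeling is compared
with the reference solution by the adjusted Rand index over the *full*
cohort — the reading of "combined … complete cluster solution" adopted here;
an `ari_scope="holdout"` mode restricts the comparison to subsample +
holdout for the alternative reading.  The cluster-to-cluster index is the
mean Euclidean distance between replicate and reference centroids under the
optimal one-to-one matching (Hungarian assignment); it is a pseudo-metric
(symmetry and identity hold; the triangle inequality is not claimed).

The LDA uses the pooled within-class covariance with a ridge of
1e-6·tr(Σ)/p (absolute floor 1e-8 so the zero-scatter noiseless case stays
solvable): subsamples of 100 with 16 items can be ill-conditioned.  Class
priors are proportional to class sizes; assignment ties go to the lowest
class index.  Replicates with an emptied or singleton cluster cannot fit the
classifier; they are recorded, skipped and excluded from the averages.

`StabilityConfig` defaults to the full-scale procedure (10,000 replicates);
tests and the acceptance script run 300–500 replicates, at which the means
are stable to well under 0.01.

**ARI convention.**  The chance-corrected index is computed from the
contingency counts.  When the expected-index denominator vanishes — which
happens only when both partitions are all-singletons or both single-cluster,
i.e. when they agree exactly as partitions — the value is 1.0 (0.0 would be
returned on pairwise disagreement, which cannot co-occur with a vanishing
denominator).  This matches scikit-learn's convention.

## 5. Group comparisons

**ANCOVA.**  Each ROI measure is modelled as intercept + group indicators +
age + sex (+ ICV for surface-area and volume measures; thickness does not
scale with head size, so ICV is excluded from thickness models — asserted
structurally in tests).  The group F statistic is the extra-sum-of-squares
comparison of the full model against the covariates-only model — equivalent
to a Type-II test since group is the only factor.  Collinearity is gated on
the condition number of the column-normalized design (raw covariate scales,
ICV ≈ 1.5·10⁶ mm³, must not masquerade as rank deficiency).  Complete cases
per measure, with the exclusion count logged.  Both raw and covariate-
adjusted group means are reported, since published tables rarely state which
is shown.

**Multiple testing and post hoc.**  Raw p-values are Benjamini–Hochberg
step-up adjusted across the 13 ROI measures.  Pairwise Tukey–Kramer
comparisons run only for measures whose FDR-adjusted omnibus p passes the
gate (default 0.05).  After ANCOVA, the post hoc compares covariate-adjusted
means: the difference's standard error comes from the model's coefficient
covariance, the studentized-range statistic is q = |diff|·√2/SE with the
model's residual df, and unequal group sizes are handled by the Kramer
form (which the coefficient-covariance route reproduces exactly in the
covariate-free case — cross-checked against statsmodels and a Monte-Carlo
evaluation of the range distribution).

**Clinical tables.**  One-way ANOVA accepts raw data or printed summary
statistics (means, SDs, ns) so published tables can be verified directly;
a zero within-group variance with equal means is flagged degenerate rather
than returning an arbitrary F.  Contingency rows use Pearson chi-square
without continuity correction, expected counts from the margins.  Of the
published demographic rows, sex, anorexia and bulimia reproduce under plain
Pearson chi-square to the printed two decimals (the anorexia row computes to
0.8850, the exact rounding midpoint of the printed 0.89); the comorbid-
anxiety, recurrence and family-history rows do not, indicating a different
(possibly covariate-adjusted) test was used for them, and they are excluded
from verification fixtures.

## 6. Synthetic cohort generator

The generator exists because participant-level data behind this kind of
study are not shareable; it emulates the *statistical structure* the
analysis assumes, not any particular dataset.

**Ordinal scores.**  Each item has a latent Gaussian with mean
3 × propensity (+ the profile's severity shift for non-neurovegetative
items) and sd `noise_sd`, rounded and clipped to {0,…,3}.  With
`noise_sd = 0` and no correlation targets every subject's vector equals its
profile's rounded expectation exactly.

**Planted subtypes.**  The default profiles mirror the three-subtype
structure: MOD (moderate severity, typical neurovegetative pattern, 40%),
SDA (severe, high insomnia and decreased appetite, 38%), SIA (severe,
increased appetite and weight gain, 22%) — prevalences in the 111:105:59
proportion.  Endorsement percentages are illustrative: the source radar
plots print no numbers, so the propensities were chosen once as plausible
values, not calibrated to any cohort.

**Opposite-polarity exclusivity.**  For each pair (decreased/increased
appetite, weight loss/gain, the three insomnia items vs. hypersomnia) a
shared per-pair direction gate — the profile's polarity, or a fair coin when
a profile endorses neither side — zeroes the disallowed side for every
subject, so no subject ever endorses both polarities.

**Correlation targets.**  A negative target ρ for a pair fixes the two named
items' endorsement probabilities through ρ² = p_a·p_b/((1−p_a)(1−p_b)) (the
exact correlation of two mutually exclusive binaries).  The solution is
closed-form, no tuning loop: the minority side — which carries the
subtype-defining symptoms — keeps its natural marginal, and the majority
side is thinned (zeroed with the complementary probability) down to the
implied value; when the natural correlation is too weak even with the full
majority side, subjects flip across to raise the minority marginal instead.
Graded score magnitudes inflate the variances slightly, so realized
correlations sit a few hundredths below |ρ| (the default cohort realizes
about −0.43 for the appetite pair targeted at −0.49 and −0.27 for weight at
−0.31).  Targets introduce Bernoulli randomness, so the zero-noise
determinism above applies only to target-free specs.

The default cohort sets **no sleep target**: under hard exclusivity and
insomnia-dominant profiles, any negative insomnia–hypersomnia correlation
implies a hypersomnia marginal below 1%, and standardizing a column with one
or two endorsers manufactures extreme outliers (|z| > 15) that hijack
Euclidean clustering — an artifact, not a feature of real data, where
hypersomnia endorsement is sizeable and exclusivity with the three insomnia
items is soft (a person can nap excessively *and* sleep badly at night).
This is the main respect in which the generator deliberately departs from
the reported correlation structure; sleep exclusivity itself is still
enforced per subject.

**ROI tables.**  Each of the 13 measures is baseline + covariate terms +
group effect + Gaussian noise.  Defaults: age ~ Uniform(15, 25) years, sex
balanced 0/1, ICV ~ Normal(1.5·10⁶, 1.5·10⁵) mm³ (no covariate
distributions are published; these are chosen once as plausible for a youth
cohort).  Baselines are plausible young-adult bilateral means; area and
volume measures get a positive ICV slope and thickness a zero ICV slope by
construction.  Residual sds default to ~9% of baseline for areas, 0.12 mm
for thickness, 8% for volumes.  The canonical planted effect is −40 mm²
anterior insula surface area in SIA, matching the reported direction and
magnitude of that deficit.

**What passing tests do and do not show.**  The generator produces
well-separated, low-dimensional planted structure; recovery there
demonstrates the machinery is correct, not that three subtypes exist in any
real cohort, and published headline values (mean ARI 0.40/0.56, 9-of-26
votes, specific ROI means) depend on unavailable participant-level data and
are not reproduced.

## 7. Problem sizes and determinism

Simulation studies in the test suite and acceptance script use desk-scale
sizes chosen as the package's defaults for verification work: cohorts of
80–300 subjects, 300–500 stability replicates, 199–999 permutations, 200
simulation repetitions for calibration checks.  At these sizes every
stochastic check has comfortable margins (e.g. the 5% calibration band
[0.02, 0.10] at 200 repetitions is the exact binomial 95% envelope around
0.05 with room to spare).  Every stochastic routine takes an explicit seed
(numpy `default_rng`); replicate seeds are spawned from a root
`SeedSequence`, so runs are bit-reproducible and label outputs byte-stable
across reruns, which the pipeline tests assert.

## 8. Known limitations

* The validity battery is a fixed, documented set of 12 indices on Ward
  partitions with Euclidean distance — not a reproduction of any particular
  software's full index catalogue or its exact method/distance
  combinations.
* The second-difference conventions for Marriot/TraceW/Rubin are the
  standard ones but conventions differ across implementations; each index's
  rule is data, not code, and can be swapped.
* The generator's hard polarity exclusivity is stricter than real
  questionnaire behaviour (see the sleep discussion above).
* ANCOVA assumes homogeneous covariate slopes across groups (no
  group × covariate interactions) and complete cases per measure; no
  site/scanner harmonization or mixed-effects modelling is provided.
* The latent-class analysis sometimes used as a companion method is out of
  scope, as are FreeSurfer segmentation and upstream MRI processing — the
  package consumes ROI tables.
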