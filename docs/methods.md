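# Methods

## The problem

Outlier samples in transcriptomic studies — swapped tubes, degraded RNA,
atypical biology — distort both differential-expression rankings and
downstream classifiers. Whether a given sample is flagged by an outlier
detector, however, depends on which other samples happen to be in the
dataset: a point that looks extreme next to one sample composition can
look ordinary next to another. A single yes/no flag therefore overstates
what the data support.

`outlierboot` replaces the flag with a *probability*. The dataset is
resampled with replacement `I` times (default 100). In every bootstrap
replicate:

1. a classical PCA is fitted on all samples of the replicate (both study
   groups jointly, top `n_pcs = 2` components);
2. the component scores are split by study group;
3. a two-dimensional outlier detector — bagplot or PCA-Grid — is applied
   to each group's score cloud;
4. the distinct sample ids present in the replicate and the distinct ids
   flagged are recorded. Duplicated bootstrap copies of a sample enter the
   detector as coincident points, but a sample counts at most once per
   replicate for both occurrence and detection.

For each sample the procedure reports the number of replicates containing
it (`n`), the number in which it was flagged (`k`), the outlier
probability `k/n`, an exact one-sided binomial p-value for
H0: p ≤ 0.5 (tail sum of the Binomial(n, 1/2) mass), and the matching
one-sided 95% Clopper–Pearson lower bound (the 0.05 quantile of
Beta(k, n−k+1); intervals are reported as [lower, 1.00]). A sample is a
*significant outlier* when p < α = 0.05. One-sided test and one-sided
bound are exact duals at p0 = 0.5: p < α exactly when the lower bound
exceeds 0.5 (asserted in the test suite for all 0 ≤ k ≤ n ≤ 100).

Samples never drawn in any replicate (possible at small `I`) are reported
with `n = 0`, missing probability, and are never significant. No
multiplicity correction is applied across samples; each sample is tested
at raw α.

Resampling is unstratified over the whole dataset by default (a
stratified option preserves group sizes). A bootstrap group that ends up
with fewer than 4 members is skipped for that replicate with a logged
warning.

## Bagplot detector

The bagplot generalizes the boxplot to two dimensions through Tukey
halfspace depth: the depth of a point is the minimum number of data
points in any closed halfplane containing it. Depth is computed exactly
by an angular argument — writing the non-coincident data as angles around
the query, the depth is the coincidence count plus `m` minus the largest
number of angles in an open semicircle, an O(m²) enumeration with no
tolerance beyond the angle computation. Coincident points (bootstrap
duplicates) count with multiplicity.

The *depth region* D_k = {x : depth(x) ≥ k} is a convex polygon whose
edges lie on lines through pairs of data points; it is computed exactly as
the intersection of the halfplanes u·x ≤ s_k(u) over all pair-normal
directions u, where s_k(u) is the k-th largest projection (iterated
Sutherland–Hodgman clipping). The *Tukey median* is the centroid of the
deepest nonempty region; when the region degenerates (collinear or
coincident data) the centroid of the deepest data points is used instead.

The *bag* interpolates between D_k* — the last region holding at least
half the points — and D_{k*+1}, by blending the support offsets with
λ = (n_k − n/2)/(n_k − n_{k*+1}), n_j being the number of points of depth
≥ j. The bag therefore contains every point of depth ≥ k*+1, no point of
depth < k*, and roughly half the points overall. The *fence* is the bag
scaled about the Tukey median by a factor (2 by default — larger factors
flag less); points strictly *outside* the fence are outliers; points on
the boundary are not. Degenerate clouds (n < 3 or collinear) yield no
flags, with a warning.

One consequence of depth-with-multiplicity worth knowing: in small
bootstrap groups the bag level k* can be as low as 2–3, and a far-out
sample drawn k* or more times forms a coincident clump of depth k* that
pulls the depth region (hence bag and fence) out to its location, so such
a replicate misses it. This is faithful to the depth semantics and fades
with group size; it is why detection probabilities of even gross outliers
sit below 1.0 at very small n.

## PCA-Grid detector

Projection-pursuit robust PCA replaces the variance objective of
classical PCA with a robust spread measure, so a few gross outliers
cannot attract the leading directions. Directions are found by a grid
search: starting from the coordinate axis with the largest robust scale,
the search sweeps the 2-D planes spanned by the current best direction
and each coordinate axis, evaluating a grid of angles per plane (90
points over [−π/2, π/2) on the first sweep, 20 on refinement sweeps) and
halving the angular window between sweeps (20 sweeps, resolving
directions to ~1e-6 radian). Components are extracted sequentially in the
orthogonal complement of the previous loadings, so loadings are
orthonormal by construction; the center is the coordinate-wise median.
The search is deterministic given the data.

The projection index is the **Qn** pairwise-difference scale by default.
Qn shares the MAD's 50% breakdown point but has 82% Gaussian efficiency
against the MAD's 37%; with the MAD index the estimated directions carry
intrinsic angular noise of roughly 10–15° at n = 500, d = 10 (the
objective is nearly flat near its maximum — a direct local polish of the
MAD field does not reduce the angle), whereas with Qn the top-2 subspace
lands within a few degrees of classical PCA on clean data. `scale="mad"`
restores the MAD index.

Samples are flagged from the robustly standardized score distance
SD_i = sqrt(Σ_j (score_ij / scale_j)²) against the square root of the
chi-square(k) quantile at level 0.975. Because the loadings are chosen to
*maximize* the robust scale, the per-component scales carry an upward
selection bias and raw squared distances sit below the nominal chi-square
reference; the squared distances are therefore rescaled so that their
median matches the chi-square(k) median — the standard consistency
correction for robust distances — restoring the nominal ~2.5% flag rate
on clean Gaussian data while remaining robust to contamination
(`recalibrate=False` disables it). A component with zero robust scale
(majority of coincident scores) contributes zero for zero scores and
infinity otherwise, with a warning, so the single-deviating-sample case
still flags correctly.

Within the bootstrap the PCA-Grid detector is applied per study group to
the classical PC scores, with k = `n_pcs` robust components, mirroring
the bagplot convention.

## Differential expression and feature selection

Raw counts are transformed to log2 counts-per-million,
log2((count + 0.5)/(libsize + 1) · 1e6), after removing transcripts whose
maximum CPM is below 1. Per-observation precision weights (the
mean–variance trend correction) are deliberately not modeled; plain
log-CPM feeds an unweighted moderated t. This is a documented divergence:
the weighting machinery is peripheral here and the moderated t on
log-CPM is the operative ranking.

The two-group moderated t shrinks per-transcript residual variances
toward a common prior by empirical Bayes. With pooled residual variances
s²_g on d degrees of freedom, the prior (d0, s0²) is estimated by moment
matching on e_g = log s²_g − ψ(d/2) + log(d/2):
trigamma(d0/2) = var(e) − trigamma(d/2) (Newton-inverted) and
log s0² = mean(e) + ψ(d0/2) − log(d0/2). The posterior variance is
(d0·s0² + d·s²_g)/(d0 + d); the moderated t divides the mean contrast by
its posterior standard error and is referred to a t distribution with
d + d0 degrees of freedom. A non-positive trigamma argument means the
variances are more concentrated than chi-square sampling noise alone
allows — the infinite-prior-df limit — and is handled as full shrinkage
to s0²; genuinely pathological inputs (non-finite moments) degrade to the
ordinary pooled t with a warning. The implementation matches an
independent reference fit (R limma `lmFit` + `eBayes`) to ~1e-12 on a
fixed two-group matrix; the reference outputs are frozen in the test
suite.

Transcripts are ranked by ascending p-value (ties: |t| descending, then
id); incremental selection takes rank prefixes (10, 20, …, 200 by
default). Multi-group data are ranked by a one-vs-rest scheme keeping
each transcript's best p-value, a documented choice since the multi-group
contrast structure is open.

## Evaluation pipeline

Three outlier-handling strategies are compared: **A** keep all samples,
**B** remove known (planted) outliers, **C** remove the bootstrap's
significant outliers. The outlier table is computed once on the full
dataset; each strategy's subset is then evaluated by repeated random
splits: 2/3 of samples train (unstratified; redrawn up to 10 times if a
class is missing), 1/3 test, 100 repetitions by default. Transcript
ranking runs inside each split on the training samples only — selection
on the full dataset would leak test information into the gene list; a
`select_on_full` switch reproduces that optimistic variant deliberately.
Every strategy receives the same evaluation seed, so identical sample
subsets (e.g. A vs C when nothing is significant) give bit-identical
performance rows.

Classifiers: linear SVM (cost 10, Platt-scaled probabilities), random
forest (500 trees, √p features per split), and LDA (Ledoit–Wolf
shrinkage toward a scaled identity when the feature count reaches the
training size, where the pooled covariance is singular). Metrics per
split: accuracy, Brier score (mean squared difference between class
indicators and predicted probabilities), and for two classes sensitivity,
specificity, PPV and NPV, with zero-denominator ratios reported missing
and excluded from averaging; multi-group runs report accuracy and
multiclass Brier only. Tables report mean ± standard error over splits.

The overlap report measures gene-list stability: per strategy, the top-n
(default 200) transcripts are recorded for every CV training split; the
report returns per-transcript selection frequencies, the two
top-n-by-frequency lists, their intersection size/percentage, and
per-transcript frequency differences.

## Synthetic data generator

The generator emulates a two- or four-group log-scale expression study:

| parameter | default | meaning |
| --- | --- | --- |
| `n_transcripts` | 1000 | transcripts d |
| `samples_per_group` | 50 | regular samples per group |
| `outliers_per_group` | 5 | planted outliers per group |
| `n_de_transcripts` | 100 | transcripts with a between-group fold change |
| `n_outlier_de_transcripts` | 50 | transcripts shifted in outlier samples |
| `baseline_mean_range` | (4, 12) | uniform law of the baseline means μt |
| `lfc_range` | (0.8, 2.0) | magnitude of nonzero log2 fold changes λt (random sign) |
| `noise_sd` | 1.0 | shared Gaussian noise sd |

Baseline means μt are uniform on [4, 12] (a typical log2-expression
range). For each non-reference group an independent subset of
`n_de_transcripts` transcripts receives the multiplicative mean shift
μt2 = μt1·2^λt. Outlier samples share one transcript subset, drawn
disjoint from the group-1-vs-2 contrast set so outliers deviate in
directions unrelated to the class signal, with group-specific λ draws;
outliers use the same noise law as regular samples — only their mean
vector differs. Expression values are Normal(μ, noise_sd). Identical
configs (including seed) reproduce the matrix bit for bit.

What the generator does *not* emulate: count-scale (negative binomial)
noise, mean–variance trends, transcript–transcript correlation, batch
effects, and library-size variation. Passing tests on this generator
therefore demonstrate the mechanics of the bootstrap, the detectors and
the evaluation pipeline under idealized Gaussian noise, not performance
on real RNA-Seq count data. Note also that multiplicative fold changes
applied to [4, 12]-scale baselines produce strong group separation;
classifiers often reach perfect held-out accuracy at the defaults, so the
strategy comparison mostly measures whether outlier removal can *hurt*.

## Problem sizes used in the checks

The test suite runs scaled-down studies chosen to keep the suite fast:
d = 300 transcripts, 30 regular + 3 outlier samples per group,
n_de = 30, n_outlier_de = 15, I = 50 bootstrap replicates for
planted-outlier recovery (10 seeds), and 25 CV repetitions with the gene
grid {10, …, 50} for the strategy comparison (20 seeds, linear SVM).
Calibration checks use n = 500, d = 10 Gaussian data; the
subspace-agreement check uses a strongly spiked spectrum (sds 8, 4, 1…)
because with a flat spectrum the top-2 subspace is not identifiable and
the comparison to classical PCA degenerates.

## Numerical choices and degenerate inputs

- Depth regions: halfplane clipping tolerance 1e-12; polygon centroids by
  the shoelace formula with a mean-of-vertices fallback for zero-area
  polygons.
- Bagplot ties at the bag level follow the λ-interpolation; points
  exactly on the fence are inliers.
- Collinearity is declared when the smallest singular value of the
  centered cloud is below 1e-12 times the largest.
- Grid search sign convention: the largest-magnitude loading entry is
  positive.
- Binomial tail sums use the scipy binomial mass directly; the
  Clopper–Pearson bound is a Beta quantile (0 at k = 0, α^(1/n) at
  k = n).
- Trigamma inversion by Newton iteration with asymptotic start values.
- CV splits that lose a class are redrawn (≤ 10 times, logged) before
  erroring.

## Known limitations

- The bagplot dialect interpolates exact depth contours; published
  implementations interpolate approximate contours, so borderline points
  near the fence can differ between implementations.
- Depth-region computation is O(n² log n)-ish per cloud via pair-normal
  clipping and is intended for the per-group cloud sizes of this pipeline
  (tens to a few hundred points), not for n ≫ 10³.
- The grid search evaluates the Qn scale O(n²)-wise per angle batch;
  robust PCA on very wide matrices (d ≫ 10³) is slow and not the
  intended use (inside the bootstrap it only ever sees `n_pcs`-dimensional
  score clouds).
- Outlier probabilities are conditional on the detector and its settings;
  the bagplot factor and the PCA-Grid quantile move the operating point
  and are not calibrated against each other.
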