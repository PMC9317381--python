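# Methods

This note records the models, parameter choices and numerical conventions
behind `olfphen`, and what the synthetic experiments do and do not show.

## The synthetic cohort

The generator is the package's stand-in for a request-only clinical cohort;
it defines the conditions every simulation-based test runs under.

**Latent model.** Fifteen olfaction variables are drawn from a multivariate
normal with unit variances. Within-block correlation r = 0.5 ties the three
questionnaire subscales, the two peanut-test distances, and the
discrimination/identification subtests; all other latent correlations are
zero. Cluster signal enters as a mean shift of ±d/2 on the latent scale
(cluster sizes 80/55 of n = 135), so a configured d is the population
Cohen's d before marginal transforms and missingness. The default profile
concentrates signal in the four sorting variables (d = +1.2, +1.3, +1.2,
+1.0; positive = more errors in cluster 1), with importance-of-application
−0.8, peanut distances −0.7, Sniffin' subtests −0.30…−0.45, and |d| ≤ 0.2
elsewhere.

**Marginals.** Thresholds, peanut distances and the post-exposure threshold
are lognormal (location/scale chosen for plausible clinical ranges: e.g.
thresholds around dilution step 7, distances around 6 cm); other variables
are affine-normal. BMI is generated as u⁻² with u normal, i.e. its
reciprocal square root is exactly normal — the transform its distribution
calls for; a plain lognormal BMI had made the ladder pick the log instead.
Age, sex and BMI carry small cluster-dependent shifts (female fraction
0.70 vs 0.49; age 28 ± 9.7 vs 34 ± 13.2 y); `demographic_shifts=False`
removes them, which together with zeroed effects gives a fully null cohort
for calibration studies. Exactly `round(0.04 · 135 · 15)` = 81 olfaction
cells are masked completely at random; covariates stay complete.

**Behavioural layer.** Raw sorting responses come from a Mallows model
centred on the correct order, sampled by repeated insertion with
φ = 1 − exp(−dispersion); dispersion 0 gives perfect sorting and the
expected footrule error grows with dispersion. Durations are lognormal
(median 60 s). This layer feeds the scoring functions; the cohort-level
generator emits the scored variables directly.

**What passing tests show.** Recovery results on these cohorts demonstrate
that the pipeline finds structure *of the planted kind*: Gaussian clusters
expressed as mean shifts with simple block covariance and MCAR gaps. Real
cohorts have discrete/bounded scores, outliers, MNAR missingness and
unmodelled covariance; performance there is not implied.

## Preprocessing

The ladder grid is the canonical {−2, −1, −½, 0 (log), ½, 1, 2}, with
negative rungs applied as −x^p to stay monotone and an offset of
1 − min(x) whenever nonpositive values meet log/root/negative rungs. The
selection criterion is the D'Agostino–Pearson omnibus p-value (χ², 2 df, on
≥ 20 observations); ties break toward the identity, then the milder
|power|. At n = 135 the neighbouring rungs of a mild lognormal win a few
times in twenty, so distributional tests of the selector are modal, not
per-seed. The retention rule drops variables, then cases, with ≥ 20%
missing cells. Imputation is chained-equation regression with random
forests (default 100 trees, 5 sweeps, seeded), targets restricted to
olfaction variables, imputed values clamped to each variable's observed
range; observed cells are never modified. Standardization uses the sample
SD (ddof = 1).

## Computed ABC analysis

Items are stably sorted descending; the curve of cumulative item fraction
vs cumulative value fraction starts at (0, 0). The A|B boundary is the
curve point nearest (Euclidean) to the ideal (0, 1); the B|C boundary sits
before the first segment whose slope drops to ≤ 1 (items below the mean
value), clipped to be ≥ the A|B boundary. Linear interpolation, exact
arithmetic on the sorted values; ties keep input order, so the partition is
deterministic and permutation/scale invariant. The cited method's optional
distribution-fitting refinements are not implemented, so agreement with
other implementations on boundary-adjacent items is not guaranteed.

## Unsupervised structure

PCA is an SVD of the centred z-matrix; eigenvalues are those of the sample
correlation matrix; components are sign-fixed so each component's
largest-|loading| is positive. Retention is Kaiser–Guttman (> 1), falling
back to one component with a warning. The variable importance z-scores the
variable × component association matrix *within each component* (the
cross-variable comparability reading of an ambiguous convention), weights
by explained-variance fraction and sums over retained components; ABC
consumes |row sum| because row sums can be negative while ABC needs
positive data — both signed and absolute versions are reported.

k-means uses k-means++ with 25 restarts, tol 1e-6, ≤ 300 iterations,
silhouettes with Euclidean distance; k ∈ {2…5} by maximal mean silhouette,
ties to the smaller k; a run is flagged structureless below a configurable
mean silhouette of 0.1 (note that pure noise at n = 135 in 6 dimensions
still yields ≈ 0.14, so the flag marks only gross failures). Bootstrap
stability redraws n subjects with replacement, re-clusters at the reference
k, and scores ARI between run labels and reference labels on the unique
resampled subjects; degenerate single-cluster runs score 0. PAM is a plain
BUILD + SWAP k-medoids on the Euclidean distance matrix, used only for the
silhouette comparison table.

**Realistic stability levels.** At the default effect profile the oracle
(true-direction) misassignment is already ~10%, so clustering ARI against
truth tops out near 0.6–0.7 and bootstrap mean ARI spreads over ~0.35–0.9
(mean ≈ 0.63 across seeds) — close to the 0.55 reported for the motivating
real cohort. k = 2 is still selected in ≈ 19/20 seeds. A stability demand
of ARI > 0.8 in ≥ 90% of seeds is not attainable under these conditions
and the corresponding acceptance check is left failing rather than the
generator being strengthened.

## Group statistics

Mann–Whitney U uses midranks; for n₁·n₂ ≤ 400 the two-sided p comes from
the exact permutation distribution of the rank sum (a subset-sum dynamic
programme over doubled midranks, so ties are handled exactly, run on the
smaller group); larger samples use the tie-corrected normal approximation.
Cohen's d divides by the ddof-corrected pooled SD, sign positive when
cluster 1 is larger. χ² on 2×2 tables applies the Yates correction for
observed cross-tabulations (sex, diagnosis vs cluster) and omits it for
the cohort-vs-population composition comparison — the two conventions under
which the published statistics reproduce exactly; the flag is explicit
everywhere. Bonferroni divides α = 0.05 by the battery size (18 =
15 olfaction + age + BMI + sex).

## Feature-selection ensemble

Hyperparameters come from 5-fold grid search by balanced accuracy: linear
SVM and logistic regression over penalty type (L1 first for the SVM, L2
with newton-cg first for logistic, so ties land on those conventions) and
C ∈ 10^{−3..3}; forests over {200, 100} trees × depth {10, 5, ∞}.
Per-method rules: SelectKBest takes the top-k one-way-F variables with k
tuned once per classifier over 1..18; SelectFromModel keeps variables with
importance (|coefficient| or impurity decrease) ≥ the mean; RFE eliminates
step-by-step to the top half; sequential selection greedily adds (from
empty) or removes (from full) the move that improves internal CV balanced
accuracy by > 1e-4, else stops. Counts accumulate over
RepeatedStratifiedKFold training folds (5 × 20 = 100 runs at study scale);
per-method ABC uses counts jointly over all runs. The final set is the ABC
"A" of the per-variable sum of A-memberships (0–17); PCA rows structurally
exclude age/sex/BMI. The whole ensemble is a pure function of
(table, labels, seed).

**Desk-scale profile.** A single CPU fit of a 100–200-tree forest at this
n costs ~0.2–0.4 s, putting the study-scale ensemble (hundreds of thousands
of forest fits inside greedy SFS) at hours of CPU. Simulation studies,
the acceptance script and the analysis drivers therefore default to
`EnsembleConfig.fast()`: 5 × 1 CV runs for count-based selectors, SFS on a
single run with 2-fold internal CV and ≤ 6 greedy moves, RFE step 4, a
k-grid stride of 2, and a 30-tree forest grid. The contract and defaults
remain the study-scale scheme; the profile trades count resolution
(0–5 instead of 0–100) for ~20 s per ensemble, and the recovery studies
show the consolidation is robust to that.

## Holdout validation

The 20% holdout is stratified per group (80/55 → 16/11) and drawn before
any tuning or selection. Each validation run re-fits on a stratified 80%
subsample of training and scores a stratified 80% subsample of the holdout
(stratification avoids empty-class fits at these sizes); features are
scaled by training-set statistics. Cells report the median and the
2.5th–97.5th percentiles over 100 runs; a cell is flagged unstable if a
class disappears from the scored subset in more than half of the runs. The
diagnosis target is normosmia vs impaired (hyposmia + any anosmia), with
classifiers re-tuned for it, and is skipped when the minority diagnosis has
fewer than 10 subjects.

## Known limitations

- The generator matches first/second moments and block structure only; no
  MNAR missingness, outliers, or discreteness of the real instruments.
- The importance formula's within-component z-scoring is noise-amplifying
  when loadings are nearly equal (near-constant columns); symmetry then
  holds in distribution, not per draw.
- Exact agreement of the ABC boundaries with other published
  implementations is not guaranteed on boundary-adjacent items.
- Bootstrap ARI of k-means on structureless data is moderate (~0.4), not
  zero; it separates strong from absent structure but is a blunt
  instrument near the boundary.
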