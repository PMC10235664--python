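# Methods

`protnet` implements a weighted correlation-network analysis of a serum
immunoassay panel, the association of the resulting protein clusters with
depression diagnosis and individual depressive symptoms, and a split-half
assessment of cluster stability.  Because the cohort data such analyses are
run on are typically not redistributable, the package ships a synthetic
cohort generator that reproduces the statistical structure the method
assumes; every stage is exercised and tested end to end on generated data.

## Preprocessing

Analytes whose missing-data fraction strictly exceeds 30 % (configurable)
are excluded.  Cells censored at a detection limit count as observed for
this rule when a limit is on file, because they remain imputable.
Imputation then proceeds in two steps: censored cells are set to their
lower/upper detection limit, and remaining missing cells to the median of
the analyte's observed, uncensored values (an even count takes the mean of
the two central order statistics).  Censored values are excluded from the
median because a value at the limit is not a valid central-tendency
observation; the alternative (including them) changes the median only when
censoring is heavy.  Finally each analyte is quantile-normal transformed:
value ← Φ⁻¹((rank − c)/(n − 2c + 1)) with the Blom offset c = 3/8 and
average ranks for ties.  The transform stabilises variance and removes the
heavy right tails typical of immunoassay concentrations; it also makes the
Pearson correlation a rank-based quantity, so the network is insensitive to
monotone re-scalings of individual analytes.

Median imputation is only defensible under (approximately) random
missingness; the generator therefore produces MCAR gaps, and nothing in
the pipeline attempts to correct informative missingness.

## Network construction and module detection

The network is unsigned: connection strength a_ij = |r_ij|^β with the
soft-threshold power β = 4 (configurable), so positively and negatively
correlated analytes are equally connected.  β is fixed by configuration;
the scale-free topology fit (log₁₀ binned degree frequency regressed on
log₁₀ mean connectivity, equal-width bins) is reported as a diagnostic,
never used as an automatic β selector.

The clustering dissimilarity is 1 − TOM by default, with
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij); `adjacency`
(1 − a) is selectable.  Analytes are clustered by average-linkage
hierarchical clustering.

Branches are decomposed into modules by a dynamic, dendrogram-shape-based
rule written for this package:

* Let q05 and h_max be the 5th percentile and maximum of the merge
  heights, R = h_max − q05 the working height range, and
  cut = q05 + 0.99·R the cut height.
* A branch qualifies when (a) it has at least `min_module_size` (default 5)
  leaves, (b) its root merge height is ≤ cut, and (c) the gap between the
  height at which it attaches to the rest of the tree and its own root
  height is at least `gap_frac`·R, where gap_frac = 0.20 − 0.05·deep_split
  (default deep_split = 2, i.e. 0.10).
* Qualifying branches whose two children both qualify are split
  recursively; otherwise the branch is emitted whole.
* A qualifying branch is finally validated statistically: its mean
  within-branch |r| must exceed `validation_z`/√(n_subjects − 1)
  (default z = 2.6).  Under global independence the sample correlation has
  scale 1/√(n − 1); in calibration runs the most correlated chance branch
  across hundreds of null panels reached 2.3 on this scale, while planted
  modules at the weakest settings the test-suite exercises stayed above
  2.9.  The check suppresses spurious modules in uncorrelated data without
  touching real ones; passing `cor=None` disables it.

The relative (range-based) cut and gap make the rule invariant to the
severe height compression that β = 4 induces on modest correlations.
Shape-only cohesion criteria (anchoring on the median or an upper quantile
of merge heights) were tried and discarded: they could not separate chance
branches from weak-but-real modules across the regimes the package must
handle, which is why the statistical validation step exists.  This
decomposition plays the role of the "tree" dynamic cut; the hybrid
(PAM-stage) variant is deliberately not implemented, and module recovery —
not replication of any particular cohort's labels — is the accepted
behaviour surface.  Ties in average-linkage merges are resolved
deterministically by the linkage implementation, so dendrograms and
partitions are reproducible bit for bit.

Modules are labelled 1..K by descending size; label 0 is "unassigned".

## Eigenproteins and module membership

A module's eigenprotein is the first principal component of its
standardized subject × analyte submatrix (computed by SVD), rescaled to
mean 0 / SD 1, with sign chosen so that the mean correlation with the
module's analytes is positive — the standard orientation; without a
convention the PC sign is arbitrary.  Variance explained is the leading
eigenvalue's share.  Module membership (kME) is the Pearson correlation of
each analyte with each eigenprotein, with two-sided p-values from
t = r√((n−2)/(1−r²)) on n − 2 df.  Mixed-sign kME within a module is
expected whenever loadings have mixed signs (unsigned network).

## Association scans

Linear models (OLS) take an eigenprotein as outcome and either the
three-level diagnosis status or a four-level per-symptom factor (control /
remitted / current-low / current-high, splitting current cases at item
score ≥ 2) as exposure, under treatment coding with controls as reference.
Covariate tiers are cumulative: base (batch, site, sex, age, education),
lifestyle (+ chronic diseases, smoking, alcohol, physical activity), bmi
(+ BMI).  Batch and site enter as fixed-effect dummies.  Missing covariates
are handled by complete-case analysis per model, with the n used recorded.
Rank-deficient designs raise an error naming the aliased columns rather
than silently dropping them.

Multiple testing is controlled by Bonferroni multiplication clipped at 1:
by the number of modules for the status scan, and by
n_symptoms × n_selected_modules for the symptom scans.  The symptom list
is configuration (default: 28 of the 30 items, excluding the two
"decreased" appetite/weight counterparts of scanned "increased" items);
the count in use is logged and recorded in every result row.  The
significance level is 0.05 throughout.

## Split-half stability

The cohort is split into disjoint halves of sizes ⌈n/2⌉ and ⌊n/2⌋
(1621 → 811 + 810), by default 1000 times.  Within each half the
inverse-normal transform is recomputed — ranks are sample-relative, and
transforming before splitting would leak cross-half information — and the
full network construction and module detection are re-run with the
full-sample settings.  The imputed full-sample matrix is reused (the
missingness filter and imputation are not re-run per half); this is a
documented choice, not an inference from any source.  Per half-sample
clustering, the module with the largest overlap with the reference module
is recorded (ties broken toward the smaller module, then the lower label);
per-analyte inclusion frequencies are counts over the 2 × iterations
clusterings.  Halves whose clustering fails are recorded and skipped;
more than 10 % failures abort the run.

## The synthetic cohort generator

Each planted module m has a latent standard-normal factor f_m per subject;
analyte j of the module is λ_j f_m + ε_j with ε_j ~ N(0, noise_sd²), a
configured fraction of loadings sign-flipped, and an analyte-specific
affine re-scaling into assay-like units.  Background analytes are pure
noise.  The default panel mirrors the intended study scale: 1621 subjects
(426 controls, 483 remitted, 712 current MDD), 171 analytes in six blocks
of 24/21/13/10/7/6 plus 90 background analytes, loading 0.55 and unit
noise, giving a mean within-block |r| near 0.23–0.28.  Missingness is MCAR
at per-analyte rates drawn from a configured range, and a lower detection
limit can be placed at a configured quantile, below which values are
flagged censored-low and set to the limit.

Symptom items are ordinal 0–3 from an ordered logit: liability = item
intercept + status effect + boost + logistic noise, with thresholds
(0, 2.5, 4.5) and status effects (0, 1.0, 2.2) for control/remitted/
current; "high endorsement" is a score ≥ 2.

Planted symptom effects are carried by a latent "affected" (immuno-
metabolically dysregulated) state rather than by a regression of item
liability on the factor.  The affected state is present in every status
group (default prevalence 0.015 in controls/remitted, 0.06 in current
MDD), shifts the designated module's factor by `effect_size` (default 3.2
SD), and expresses symptomatically only in current MDD: affected current
subjects endorse the designated items with probability ≈ 0.95 (unaffected
current: ≈ 0.001) and receive a mild liability boost (0.8 logits) on every
other item.  This architecture is what makes the designed contrasts clean:

* non-designated items are (conditionally on status) independent of the
  factor, so their scans carry only the small status-borne elevation;
* the low-endorsement groups of designated items consist almost entirely
  of unaffected subjects, so the low-vs-control contrast is null — the
  direct analogue of high symptom endorsement, not depression per se,
  driving the association;
* the excess affected prevalence in current MDD produces a modest overall
  case-control elevation of the planted module (z ≈ 2–3), the borderline
  association the status scan is designed to flag.

A direct additive status shift on the factor (`status_factor_effect`,
default 0) is available but leaks into every item's contrasts; an additive
formulation in which the factor raises endorsement probability among
current cases was rejected at the design stage because it provably cannot
give a nonzero high-side contrast together with null low-side and
null-item contrasts (P·(μ_H−μ_C) = −(1−P)·(μ_L−μ_C) forces leakage).
The price of the affected-subgroup design is that designated items are
rare (≈ 1.5 % high endorsement among current cases, against ≈ 30 % for a
typical real symptom) and the factor shift of the affected subgroup is
large (3.2 SD); prevalence 0.015/effect 3.2 were fixed by a power
calculation (≥ 6σ designed high-side contrast at Bonferroni α/28 with a
Poisson-stable affected count) before the acceptance checks were frozen.
BMI is optionally coupled to planted factors (default 1.5 kg/m² per SD),
giving the mediated path that the BMI adjustment tier attenuates.
Covariates have plausible marginals, some status-correlated; batch (26
levels) and site (5 levels) are uniform categoricals.  A single global
seed feeds a per-component seed sequence, so outputs are bit-reproducible
and sub-streams independent.

What the generator does not emulate: assay plate drift, informative
(non-MCAR) missingness, correlated endorsement between arbitrary item
pairs beyond the shared status and affected-state liabilities, and
longitudinal follow-up.  Passing tests therefore demonstrate correctness
of the pipeline's behaviour under the factor-model assumptions, not
robustness to assay artefacts absent from the generator.

## Problem sizes in the test-suite and acceptance script

Simulation-based checks run at reduced but structure-preserving sizes
chosen as this package's own test design: module recovery at n = 800 with
blocks of 15/10/8 among 50 analytes over 50 seeds; type-I calibration of
the status scan over 200 cohorts of n = 1600 with two null modules;
symptom-scan recovery over 50 cohorts of n = 1621 with the 24/21 block
pair; stability at 50 iterations, with noise levels 1.2/1.6/2.0 spanning
the regime where half-sample detection degrades (at unit noise, halves of
800 subjects recover a 21-analyte module essentially always, so
degradation only becomes visible beyond noise ≈ 1.4).  The acceptance
script runs the full default cohort once (171 analytes, 1621 subjects,
200 stability iterations) plus the calibration summaries.

## Known limitations

* The branch decomposition is this package's own variant of dynamic tree
  cutting; on real cohorts its labels will differ in detail from other
  implementations, and the deep-split/gap parameters trade resolution
  against stability (the package reports, rather than resolves, this
  sensitivity).
* Only unsigned networks, average linkage and Pearson correlations are
  implemented; no module merging by eigenprotein similarity, no blockwise
  decomposition for very large panels, no FDR alternatives to Bonferroni.
* The eigenprotein is a linear one-factor summary; modules whose leading
  eigenvalue share is small are summarised poorly, and `variance_explained`
  should be inspected.
* Complete-case covariate handling can shrink n silently in heavily
  missing phenotype tables; the per-row `n_used` field is the guard.
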