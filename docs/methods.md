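# Methods

## Scope and data model

`hippodx` analyzes morphometric feature tables: one row per subject with a
group label (healthy control `HC`, right-HS `RHS`, left-HS `LHS`), an
estimated total intracranial volume (TIV, mm³), and named regional
measures tagged as volumes (mm³) or cortical thicknesses (mm), each with a
laterality (`left`, `right`, `bilateral`, `global`). The canonical
internal unit for volumes is mm³ throughout; parsers normalize inputs
printed with thousands separators, and volBrain-style reports carrying
both absolute and percent columns are checked for internal consistency
(disagreement beyond 1% relative tolerance triggers a warning and the
absolute value is kept as canonical, since percent columns are derived
quantities). Group labels always come from an explicit labels file or
argument, never from filenames. Parsing is strict by default; a lenient
mode logs and skips malformed rows.

## Derived statistics

* **%TIV normalization** `V × 100 / TIV` removes head-size variation,
  the dominant covariate for regional volumes.
* **Asymmetry index** `AI = (R − L)/((R + L)/2) × 100` (positive =
  rightward). It is antisymmetric under side exchange and bounded in
  (−200, 200); a zero volume on one side saturates the index at ±200 with
  a warning rather than producing NaN, because tiny subfields can be
  segmented to zero voxels in severely atrophic hippocampi. Both sides
  zero is an error.
* **z-scores** standardize a subject's %TIV value by the healthy-control
  mean and sample SD; controls scored against their own reference have
  mean 0 and SD 1 by construction.
* **Reference ranges** use the sample SD (n−1 denominator) and the
  t-quantile interval `mean ± t_{n−1,(1+level)/2}·sd/√n`, the convention
  of mainstream statistics packages. At the group sizes involved
  (n ≥ 22), t- and z-based intervals differ by under 2%, which is inside
  every downstream tolerance.
* **Group asymmetry** is reported as the mean of per-subject indices —
  this is how grouped asymmetry tables are conventionally read — and the
  index of the group means is exposed alongside (`asym_of_means`); the
  two differ whenever volumes and asymmetries co-vary.

## ROC analysis

AUC is computed as the Mann–Whitney pair-ordering probability using
midranks, which makes it exactly equal to exhaustive pair counting with
ties at ½ (a property the test suite asserts against a brute-force
oracle). Curves have one vertex per distinct score, so the trapezoidal
area equals the pair-counting AUC exactly. The "optimal
sensitivity/specificity" operating point is the Youden-J maximum — the
standard choice when no cost ratio is specified — with ties broken toward
higher sensitivity and then toward the smaller-magnitude threshold; the
reported reference value is the midpoint between the adjacent distinct
scores spanning the chosen vertex, so it is always attainable in the
observed score range. Patients form the positive class; volumes
discriminate with lower values positive, and the signed asymmetry index
with the lesion-side tail positive (more negative for right-HS, more
positive for left-HS).

## Random-forest validation

The classifier matrix drops whole-brain "global" summaries (they carry no
regional information), excludes asymmetry-derived columns (the forest
sees both hemispheres, so laterality is represented implicitly), divides
volumes by TIV (×100), and passes thickness through unscaled — thickness
divided by a volume would be dimensionally odd, and only volume measures
need head-size adjustment.

Forests use 2000 trees by default, mtry = √(feature count), and nodes are
expanded until pure or smaller than two samples. Cross-validation is
Monte-Carlo: stratified 80/20 shuffle-splits (stratification preserves
class proportions, keeping every class present in each fold, which is
what "balanced" resampling needs to mean at these group sizes).
Progressive feature elimination reuses the *same* splits at every feature
count; Gini importances are averaged across splits before each
elimination (pooling stabilizes the ranking), the single worst feature is
dropped per iteration, and ties are broken lexicographically by name for
determinism. The working feature count is chosen by a one-standard-error
rule — the smallest count whose mean accuracy is within one SE of the
best point — a deterministic surrogate for visually picking the start of
the accuracy plateau. The final evaluation runs 200 splits: accuracy is
averaged; the confusion matrix is accumulated over test folds; a
subject's class-probability vector is the mean of forest vote fractions
over the folds where it was held out (subjects never held out are
reported missing with a warning); one-vs-rest ROC curves are computed on
those averaged probabilities, macro-averaged for the multiclass task; and
per-fold importances are reported relative to the trivial level 1/N, so a
value below 1 marks a feature less informative than average.

Three tasks are standard: HC vs all patients (sides merged), left- vs
right-HS, and the three-group problem. A master seed deterministically
derives per-stage and per-fold seeds (SHA-256 of seed and stage name,
reduced below 2³¹), so every pipeline stage is bit-reproducible.

## Synthetic cohorts

The packaged parameter file transcribes published group reference values
— mean and 95% CI of each region's %TIV volume per hemisphere and of the
per-subject asymmetry index — for two volumetry methods (`FS`:
whole hippocampus + 12 subfields; `vB`: whole hippocampus + 5 subfield
groupings) and three groups (61 HC, 22 RHS, 35 LHS). SDs are
back-derived as `CI half-width × √n / 1.96` (z rather than t; <2% error
at these n).

Per subject the generator draws TIV ~ N(1.5·10⁶, 1.5·10⁵) mm³ truncated
positive, and per region a bilateral level
m ~ N((right+left)/2, pct_sd) truncated positive together with an
asymmetry a ~ N(asym_mean, asym_sd) truncated to (−200, 200); the sides
are reconstructed as `right% = m(1 + a/200)`, `left% = m(1 − a/200)`, so
the per-subject asymmetry index reproduces `a` identically and the
implied side means match the printed ones to first order. Sampling the
(level, asymmetry) pair — rather than independent sides — is essential:
independent hemispheres would inflate the asymmetry variance far beyond
the published CIs. The level SD is taken as the mean of the two
CI-derived side SDs; reconstruction adds a small side-variance
contribution of order `m·asym_sd/200`, a few percent at most. Regions
are sampled independently of one another and subfields are not
constrained to sum to the whole hippocampus, because no inter-region
covariance is published; a real cohort's subfields are strongly
correlated, so classifier accuracy on synthetic cohorts upper-bounds, and
does not estimate, real-data accuracy. Nuisance features (default 20
bilateral volumes, 40 thicknesses) are drawn i.i.d. from per-feature
Gaussians whose parameters are drawn once and shared by all groups, so
they are exchangeable across groups and carry no diagnostic signal. %TIV
distributions are primary and absolute volumes follow from the sampled
TIV, so absolute-volume (mm³) cutoffs are reproduced only approximately.
For a few of the smallest subfields the published absolute values are on
a scale inconsistent with their %TIV columns; the %TIV columns are
treated as canonical and the absolute transcriptions are informational
only.

Fixture writers emit FreeSurfer-dialect stats files and volBrain-dialect
CSVs with `repr` decimal text, so the read-back is numerically exact and
the ingest path is testable as an identity against the simulation path.

## Problem sizes and numerical choices

The reproduction suite replicates hippocampal discriminator AUCs with 200
Monte-Carlo replicates at the published group sizes, and checks generator
asymmetry marginals with 5000 simulated subjects. The forest validation
on the default cohort (86 features, 118 subjects) runs the elimination
stage with 15 splits × 250 trees and the evaluation stage with 200
splits × 500 trees; on a cohort this strongly separated, accuracy is flat
in tree count beyond a few hundred trees and in split count beyond a
dozen, so these sizes trade only negligible Monte-Carlo noise. The
pipeline defaults remain 30 elimination splits and 2000-tree forests.

Degenerate inputs are rejected early: non-positive TIV, single-class ROC
input, classes with fewer than two members, inverted CI bounds. All
stochastic stages accept explicit seeds; derived seeds are stable across
processes (no reliance on Python's randomized string hashing).

## Known limitations

* The generator models marginal distributions only; no age/sex structure
  (published covariate tests found none after TIV correction) and no
  inter-region covariance.
* Absolute-volume cutoffs depend on the simulated TIV distribution and
  are approximate by design.
* AUC confidence intervals (e.g. DeLong) are not implemented; the
  validation reports Monte-Carlo dispersion instead.
* Classification metrics on synthetic cohorts are upper bounds for
  real-data performance, not estimates of it.
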