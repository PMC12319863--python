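# Methods

## The analysis in brief

The pipeline tests whether multi-voxel activity patterns evoked by eight
visually presented body parts — hand, foot, arm, leg, chest, waist, upper
face (UF), lower face (LF) — are organized into three categories in a
body-selective cortical region: action effectors {hand, foot, arm, leg},
faces {UF, LF}, and non-effector torso parts {chest, waist}. The
measurement is a split-half representational dissimilarity matrix (RDM)
per subject; the test statistic is the ANOSIM R of the hypothesized
partition against an exhaustive null over all alternative partitions of
the same shape. Group comparability is assessed with a Mantel test on
group-mean RDMs and a mixed ANOVA on within/between-group RDM
correlations; individual differences with Spearman correlations between
per-subject R and trait scores; and the category structure is confirmed
by three-class SVM decoding with a permutation null.

## Synthetic cohorts

Because real participant data of this kind are not publicly shareable,
the `bodyrep.cohort` module generates cohorts with the statistical
structure the analysis assumes, and all tests run against that ground
truth.

Per subject, the beta pattern for condition c in run k is

    beta[k, c, v] = mu_cat(c)[v] + delta_c[v] + eps[k, c, v] (+ shift)

where `mu_cat(c)` is a per-voxel standard-normal pattern drawn once per
subject for the condition's category and scaled by `category_separation`;
`delta_c` is a condition-specific normal offset scaled by
`condition_separation`; `eps` is i.i.d. N(0, run_noise_sd²) run noise;
and `shift = group_shift` for ASD-like subjects (default 0: the two
groups share one generative geometry). Drawing the mean patterns from a
per-voxel standard normal guarantees nonzero voxel variance, so the
Pearson correlations underlying the RDM are always defined. The
whole-body localizer condition gets its own mean pattern and the chair
condition its negation, making the whole-body-vs-chair contrast maximal
for ROI localization. With `category_separation >> condition_separation`
and zero noise, the hypothesized partition provably attains the maximum
ANOSIM R over all 420 models — the identifiability case the acceptance
checks use.

Defaults mirror the study design: 23 subjects per group, 4 runs, 10
conditions, and 33 voxels (an 8-mm-diameter sphere at 2-mm isotropic
resolution contains 33 voxels). Trait tables (age, FSIQ, SRS, AQ, four
Sensory Profile subscales) are drawn from group-specific normal
distributions whose means/SDs default to the study population's
demographic summary (e.g. AQ 16.0 ± 7.0 TD-like, 33.0 ± 5.0 ASD-like).
Traits are independent of the neural patterns unless an explicit
`coupling` coefficient mixes a standardized neural score into every
trait, which exists solely to make brain–trait correlation recovery
testable.

What the simulator does *not* model: anatomy, retinotopy, spatial noise
correlations, scanner artifacts beyond low-frequency drift and AR(1)
noise, or individual stimulus images. Passing tests therefore certify
the statistical machinery — estimators, test calibration, cross-validation
hygiene — not robustness to real-data confounds like motion-correlated
signal or susceptibility dropout.

## Design and GLM

One run is 20 blocks of 12 s (10 conditions × 2 repetitions) with
fixation baselines of 27 s before block 1, 12 s after blocks 5/10/15,
and 15 s after block 20: 318 s = 106 volumes at TR 3 s. Condition
boxcars are built at 0.1 s resolution (the microtime resolution is a
package choice), convolved with the canonical double-gamma HRF (response
delay 6 s, undershoot delay 16 s, dispersions 1/1, ratio 6, length 32 s)
and sampled at volume onsets. High-pass filtering at 1/128 Hz is
implemented as discrete-cosine regressors inside the design matrix
(floor(2·318/128) = 4 columns), keeping the fit a single least-squares
problem; because OLS is a projection, drift in the DCT span leaves
condition betas untouched. AR(1) prewhitening is optional and off by
default: a single coefficient is estimated from pooled residuals
(Yule–Walker) and the model refit on transformed data — a pooled
approximation to restricted-ML autocorrelation modeling. Global signal
scaling (proportional scaling of a run to grand mean 100) is available
but irrelevant to noiseless tests. Condition regressors are not
mean-centered; the constant column carries the intercept.

## ROI conventions

Sphere membership uses the voxel-center rule: a voxel belongs to the ROI
when its center lies within `diameter/2` of the ROI center, inclusive.
ROI centers are accepted as given coordinates (taken from prior work to
avoid circular selection); coordinate-system conversion is out of scope.
Individual localization thresholds the t map inside the sphere at the
upper-α t quantile (α = 0.01 uncorrected); extent is reported both as a
voxel count and as mm³ (count × voxel volume), since published "size"
tables are ambiguous between the two conventions.

## RDM construction

Runs are 1-indexed; "odd" means runs 1 and 3, "even" runs 2 and 4.
r_ij is the Pearson correlation across ROI voxels between the odd-half
mean pattern of condition i and the even-half mean of condition j. The
split-half matrix is asymmetric, so D = 1 − (r_ij + r_ji)/2 — averaging
is the standard symmetrization and is required by the symmetric-input
contracts of ANOSIM and Mantel. The diagonal (1 − r_ii, split-half
reliability) is stored but never used in inference. RDM entries lie in
[0, 2]; the RDM is invariant to common positive affine transforms of the
betas.

## ANOSIM with an exhaustive partition null

For M = 28 pairwise dissimilarities ranked with average ranks (the
rank-statistics default for ties),

    R = (r̄_B − r̄_W) / (M/2)

where r̄_B, r̄_W are mean ranks of between- and within-category pairs.
R is rank-based, hence invariant to strictly monotone transforms of D.
The null enumerates all 8!/(4!·2!·2!) = 420 labeled assignments of
conditions to the three categories; p = (# models with R ≥ observed)/420,
observed included, so the minimum p is 1/420. Because swapping the two
size-2 category labels never changes R, the 420 values comprise 210
equal twins and the effective floor for a strict winner is 2/420 ≈ 0.005
— which is why a perfectly clustered geometry reports p = 0.005 rather
than 1/420 ≈ 0.0024. Group-level ANOSIM runs on the group mean RDM; the
same statistic per subject feeds the trait analysis.

## Mantel test

r is the Pearson correlation of the two RDMs' 28 off-diagonal entries;
the null permutes the condition labels of one matrix, by complete
enumeration of all 8! = 40,320 relabelings (feasible at n = 8; a
Monte-Carlo scheme exists for larger matrices). The test is one-sided
(p = fraction of permuted r ≥ observed, identity included), matching the
directional question "are the two geometries similar?".

## Group similarity and traits

Each subject's off-diagonal vector is correlated with (i) the
leave-one-out mean RDM of the subject's own group and (ii) the full mean
RDM of the other group; correlations are Fisher-Z transformed
(Z = atanh r) and analyzed with a mixed two-way ANOVA (correlation type
within-subject, group between-subject). Note one inherent asymmetry of
this published procedure: the within reference averages n−1 matrices and
the between reference n, so the two correlation types can differ
slightly even under identical group geometries.

Trait correlations use Spearman's ρ (Pearson on average ranks) with
Bonferroni correction over a default family of 16 (8 traits × 2
hemispheres — the full analysis family; the family size is configurable
because the published correction's family is not stated).

## Decoding

Linear SVM, C = 1, one-vs-one multiclass (scikit-learn SVC defaults
pinned), no feature scaling by default (betas share a scale within
subject; per-fold z-scoring is available). Leave-one-run-out: 24
training samples (12 effector / 6 face / 6 non-effector), 8 test
samples. Each of the default 100 bootstrap draws subsamples every
training class without replacement to the minority count (6), fits the
SVM, and predicts the held-out run; accuracies are averaged over draws
and folds (averaging, rather than voting, is the chosen aggregation).
Chance is 1/3: training sets are exactly balanced, so no class prior
leaks into the unbalanced (4/2/2) test run. The permutation null decodes
under each of the 420 condition-to-category assignments with the same
seeds; p = fraction of null accuracies ≥ the hypothesized assignment's,
itself included. Seeds derive per fold from one master seed.

## Classical statistics

Welch's t (Satterthwaite df), pooled-SD Cohen's d, Pearson χ² with
Cramér's V (continuity correction off by default), two-way ANOVA
(between-subjects via type-II SS; mixed with one within factor), partial
η² = SS_e/(SS_e + SS_err) and generalized η² (error SS summed over
strata) both always emitted since published reports mix the two,
Fisher Z, Spearman with Bonferroni, framewise displacement
FD_t = Σ|Δtrans| + r·Σ|Δrot| with r = 50 mm (the conventional rotation
radius; the source method leaves it implicit), and the one-sample t.
All p-values are two-sided except the intrinsically one-sided
permutation tests (ANOSIM, Mantel, decoding).

## Numerical choices and degenerate inputs

- Permutation p-values always count the observed arrangement (p > 0) and
  compare with a 1e-12 tolerance so exact ties count as ≥.
- Zero-variance patterns make correlations undefined: RDM construction
  raises with the offending condition and half; group t maps mask
  zero-variance voxels with a warning; constant traits report ρ as NaN.
- MDS is metric SMACOF with seed-controlled restarts; it is
  visualization-only and no inferential number depends on it.
- The simulator's generators are pure functions of (config, seed,
  subject index) via independent named substreams, so any subject can be
  regenerated in isolation.

## Problem sizes in tests and acceptance runs

Test and acceptance cohorts are scaled to keep the suite fast while
leaving conclusions unchanged: identifiability and exhaustive-ANOSIM
checks use 1–4 subjects at 30 voxels (deterministic, size-independent);
decoding chance calibration uses 24–40 pure-noise subjects at 30 voxels
(standard error of mean accuracy ≈ 1.1–1.5 percentage points); the
monotonicity sweep uses 8 subjects per separation level with common
random numbers across the grid, which makes the trend essentially
deterministic. The full 23-per-group scale is the library default and
runs in minutes, not hours.

## Known limitations

- The exhaustive nulls are specific to 8 conditions in a 4/2/2 partition;
  other shapes enumerate correctly but the 420/210 degeneracy discussion
  applies only when exactly two categories share a size.
- The mixed ANOVA supports one within- and one between-subject factor
  (all the pipeline needs); general factorial repeated measures are out
  of scope.
- The pooled AR(1) prewhitening is a one-coefficient approximation, not
  voxel-wise or spatially regularized autocorrelation modeling.
- The simulated 1-back behavioral task exists only as trait-style summary
  tables; stimulus-level behavior is not modeled.
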