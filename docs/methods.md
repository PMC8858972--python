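# Methods

`glycofib` implements an end-to-end analysis for antibody-array MALDI
imaging of immunoglobulin N-glycans: from per-pixel spot spectra to
compositional glycan profiles, through univariate screening and
redundancy-aware feature elimination, to cross-validated evaluation of a
fibrosis-stage biomarker panel. This note records the models, the defaults
and why they are set as they are, and what the synthetic data do and do not
establish.

## Glycan model and mass engine

N-glycans are represented as monosaccharide compositions over the constant
trimannosyl-chitobiose core (2 core GlcNAc + 3 Man). Oxford names follow
the grammar `A<d>[B]G<d>[S<d>][F]`; `F` is accepted before or after the
sialic-acid block and canonicalized to last position. Validation enforces
antennae ≥ galactoses ≥ sialic acids. Only compositions are modeled —
linkage, arm position and other isomerism are out of scope, as is
derivatization chemistry.

Monoisotopic neutral masses are residue sums (HexNAc 203.079373, Hex
162.052824, dHex 146.057909, NeuAc 291.095417 Da) plus one water
(18.010565 Da) for the free reducing end; values are fixed 6-decimal
monoisotopic constants, with no average-mass mode. Positive-mode singly
charged adducts add 1.007276 (H⁺), 22.989218 (Na⁺) or 44.971160 (2Na−H)
Da. Because released, underivatized glycans in positive-mode MALDI
ionize predominantly as sodium adducts, the default panel adduct is
[M+Na]⁺ for neutral species and [M+2Na−H]⁺ for sialylated species
(the sodiated carboxylate salt); both are overridable per panel entry.

## Spot quantification

Each capture spot is a set of centroided per-pixel spectra. The fixed
order of operations is: (1) TIC-normalize every pixel (sum of intensities
scaled to 1), (2) sum centroid intensity within a ±10 ppm window around
each panel glycan's theoretical m/z ("peak area"; centroided data assumed,
profile-mode integration not implemented), (3) average areas over the
spot's pixels, (4) express each glycan as a percent of the spot's panel
total (0–100, the "relative percentile"). Normalizing before averaging
makes the result invariant to per-pixel gain; closing per capture channel
(not across channels) reflects that each antibody spot is an independent
capture with its own total signal.

The 10 ppm default window suits FT-ICR-grade mass accuracy; it is
configurable. If two same-channel panel windows overlap, shared centroids
are counted for both entries and a warning names the collision —
transparency over silent reassignment. A spot with no signal yields an
all-zero profile plus a warning rather than an error.

## Synthetic cohorts

No patient-level data are available, so the generator reproduces the
*statistical structure* the analysis assumes: three fibrosis groups —
no fibrosis (healthy + METAVIR 0, n=41), early–moderate (stages 1–2,
n=28), advanced/cirrhosis (stages 3–4, n=43) — with per-sample METAVIR
stages drawn in the cohort's proportions (38/3, 10/18, 6/37), and five
capture channels (IgG, IgG1–IgG4) of 11 glycan features each (55 total).

Per sample and channel, log-abundances are `baseline + group shift +
N(0, σ)` closed to percentiles summing to 100 (logistic-normal). A
Dirichlet would couple mean shifts and correlations; the logistic-normal
lets both be set independently, which the elimination stage's correlated
pairs require. Baseline percentiles approximate a healthy IgG Fc profile
(agalactosylated/monogalactosylated core-fucosylated bi-antennary species
dominant, minor bisected and sialylated species).

Planted features mirror the seven-glycan fibrosis signature (A2G2F,
A2BG0F on IgG; A2G1F, A2G2S1 on IgG1; A2G1F, A2G0F on IgG2; A2BG1F on
IgG3) with timing classes: *early* features shift at the group 1→2
transition and plateau, *late* only at 2→3, *both* at both transitions
(A2BG0F rises progressively; galactosylated and sialylated species fall).
Defaults: effect 1.0 log-units per affected transition against σ = 0.5
intra-sample noise — a strong but clinically plausible signal consistent
with the high discrimination this kind of panel achieves. Two decoy twins
(IgG.A2BG2F twinning IgG.A2BG0F; IgG1.A2G2 twinning IgG1.A2G1F) share
their partner's noise deviation plus extra noise (σ = 0.25) and carry a
0.6-attenuated copy of the partner's shift: dependent enough to be the
top Hoeffding-D pair, informative enough to pass the univariate screen,
yet always weaker than the partner. All randomness flows through one
seeded generator; the seed is stored in the ground-truth record.

Synthetic spot spectra place a 9-point Gaussian centroid cluster (σ =
3 ppm) at each panel m/z with total intensity proportional to the profile
value times a lognormal per-pixel factor, per-peak lognormal noise of
scale 1/SNR, and a sparse uniform baseline; coincident centroids are
merged. The generator does **not** emulate instrument drift, isotopic
envelopes, matrix clusters, in-source decay, demographic covariates or
batch effects — so passing tests establish correctness of the
computational pipeline under the assumed model, not robustness of the
biomarker on real sera.

## Univariate screen

Per feature, classical one-way ANOVA over the three groups (F with k−1,
N−k df); features with p > α = 0.05 are discarded, uncorrected for
multiplicity by design (the screen is a permissive pre-filter; an
FDR-corrected variant can be layered on by the caller). Percentiles enter
the ANOVA untransformed. Post-hoc adjacent-group contrasts (1 vs 2, 2 vs
3) use Tukey's HSD by default (pairwise Welch t with Bonferroni as an
alternative; `posthoc="none"` skips the follow-up when only the F-screen
is needed, e.g. large calibration studies). Timing classification: *early*
if only the first contrast is significant, *late* if only the second,
*both* if both, *indeterminate* otherwise (logged). Which post-hoc test is
"right" is genuinely open; it is a recorded configuration choice.

## Hoeffding's D and feature elimination

Redundancy is measured by the scaled Hoeffding D statistic of
dependence,

    D = 30 [ (n−2)(n−3) D1 + D2 − 2(n−2) D3 ] / [ n(n−1)(n−2)(n−3)(n−4) ]

with D1 = Σ Qᵢ(Qᵢ−1), D2 = Σ (Rᵢ−1)(Rᵢ−2)(Sᵢ−1)(Sᵢ−2), D3 = Σ
(Rᵢ−2)(Sᵢ−2)Qᵢ, where R, S are midranks and Qᵢ counts points strictly
below-left of point i with the standard half-weight convention for ties
(½ for a tie in one coordinate, ¼ in both; midranks alone do not define
Q, so the convention is part of the definition here). D is symmetric,
invariant under strictly increasing marginal transforms, equals 1 for any
tie-free monotone relationship and ranges over [−0.5, 1]. n ≥ 5 is
required; constant variables are rejected as degenerate. The
implementation is validated against a naive O(n²) evaluation written from
first principles.

The elimination loop, per iteration: recompute the full similarity matrix
over surviving features (cheap at this scale — recomputation avoids stale
entries), take the off-diagonal argmax (exact ties broken
lexicographically for determinism), rank both members with a seeded
random-forest importance, drop the weaker member (never the stronger —
enforced structurally), then score the reduced panel by repeated
stratified 3-fold CV accuracy. One feature is removed per full iteration;
removing several pairs per pass is a plausible alternative reading of the
procedure, but one-per-iteration is the cleaner operational definition
and is what is implemented.

Importance defaults to mean Gini-impurity decrease from a 500-tree forest
with √p features per split — fast, deterministic given the seed, and the
convention of the classic randomForest implementation; permutation
importance is available (`importance="permutation"`) where impurity's
bias toward high-cardinality features is a concern (not an issue for
same-scale percentile features).

Stopping rule ("consistently and dramatically deteriorated",
operationalized): stop when the CV accuracy falls more than δ = 2
percentage points below the best mean achieved for 2 consecutive
iterations, or at `min_features` = 5; return the **best**-scoring panel
seen, preferring the smaller set on ties. The stopping score uses 5
repetitions of stratified 3-fold by default: enough to stabilize the mean
at this cohort size while keeping an elimination run to seconds; δ,
patience, repetition count and `min_features` are configurable. Because
the best-so-far reference is a maximum of noisy estimates, the rule is
conservative (tends to stop early rather than late); the returned panel
is the best-scoring one regardless of where the loop stopped.

## Evaluation

Pairwise binary random forests are refit per comparison (1 vs 2, 2 vs 3,
1 vs 3; optionally the METAVIR regrouping healthy/0/1 vs 2/3 and 2/3 vs
4) — pairwise refits rather than a sliced multiclass model, since
discrimination is assessed pairwise. Four CV schemes: apparent (train =
test, optimistic by construction, reported for completeness), LOOCV,
"3-fold random subsampling" (200 stratified 2:1 train/test splits) and
"repeated 3-fold" (200 full stratified 3-fold partitions); repeated
schemes report across-repetition means and SDs. All folds are stratified
so training folds always contain both classes.

AUC is the Mann–Whitney statistic; its 95% CI uses DeLong's
placement-variance estimator (normal-theory, clipped to [0, 1];
zero-variance degenerate cases collapse the interval onto the point
estimate). A stratified percentile bootstrap is available as an
alternative. Operating points: among observed-score thresholds achieving
specificity ≥ 90% (no ROC interpolation), the one maximizing sensitivity;
accuracy, PPV and NPV are computed there, with PPV/NPV using observed
prevalence unless an external prevalence override is given.

## Numerical and degenerate-input choices

- Peak windows: empty window → area 0 (logged), not an error; all-zero
  spectrum → error at TIC normalization.
- ANOVA: all-values-constant and zero-residual-with-distinct-means are
  rejected as degenerate; identical group means with spread give F = 0,
  p = 1.
- Hoeffding D: exact tie handling as above; n < 5 rejected.
- Elimination importance ties: drop the lexicographically later label.
- Repeated CV schemes derive per-repetition model seeds from the config
  seed, so every run is bit-reproducible.

## Problem sizes used in the test suite and acceptance script

Statistical checks run at the cohort scale of the study design (groups
41/28/43, 55 features) over 20 seeds, with 100-tree forests for
simulation-scale runs (the library default remains 500); formula-level
checks (ranks, masses, AUC examples) are exact. The calibration study
uses 20 null cohorts of 200 features. These sizes are the package's
reproducibility baseline; all are parameters, and larger runs only
tighten the Monte-Carlo error.

## Known limitations

- Compositional profiles only; no isotope-envelope deconvolution, so
  overlapping isotopic patterns of near-isobaric glycans are not
  resolved.
- The logit/transformation option for bounded percentiles before ANOVA is
  not implemented; percentiles enter untransformed.
- The synthetic generator's realism limits (above) mean acceptance is
  parameter-recovery and calibration, not reproduction of patient-data
  effect sizes; published patient-level AUCs are not reproducible desk-side
  because the underlying serum cohort is not deposited.
- LOOCV class-imbalance pessimism: under a null cohort LOOCV AUCs fall
  slightly below 0.5 on average (the held-out sample depletes its own
  class in training); this is a property of the scheme, not a bug.
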