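# Methods

This note documents the models, numerical conventions and design choices
behind `thyrosig`, and what its synthetic-data tests do and do not show.

## Problem setting

The pipeline targets two-class discrimination (benign vs. papillary
carcinoma) of thyroid nodules from the metabolomic profile of liquid-based
cytology fluid. The regime it is designed for is small and unbalanced:
tens of samples (the reference cohort is 56 benign / 22 malignant),
thousands of aligned LC-MS ions before filtering, a few thousand after,
and a target signature of ~15 ions. Everything downstream of peak picking
is in scope; raw spectral processing (centroiding, chromatogram building,
RT calibration) is expected to have been done by a dedicated tool and is
deliberately out of scope — the pipeline starts from per-run peak lists.

## Alignment

Cross-run alignment is a greedy join: runs are processed in lexicographic
`run_id` order; each peak either joins the existing feature minimizing the
combined distance `ppm/mz_tol + |ΔRT|/rt_tol` (subject to both tolerances,
default 10 ppm and 1 min) or founds a new feature. Within a run,
candidate (peak, feature) pairs are resolved best-score-first, so a run
contributes at most one peak per feature; consensus m/z and RT are
intensity-weighted means over member peaks, refreshed after each run.
Greedy join alignment is order-dependent by construction; fixing the run
order makes it deterministic. On inputs whose true ions are separated by
more than the tolerances (the regime the tolerances are chosen for), the
result coincides with exhaustive single-linkage clustering, which the test
suite checks against a union-find oracle.

## Adduct arithmetic and annotation

Only proton adducts are considered: neutral mass = m/z − 1.00727646 Da in
positive mode, + 1.00727646 Da in negative mode (CODATA proton mass; the
electron mass is neglected, a ~0.5 mDa effect far below the annotation
tolerance at these masses). A feature is annotated with every compound
whose monoisotopic mass lies within 15 ppm of the feature's neutral mass;
multiple matches are all retained, ranked by |ppm error|, since mass alone
cannot resolve isomers. Molecular-formula masses are computed with
pyteomics.

## Ion-selection cascade

Stage order: adduct annotation → mean intensity → blank ratio → optional
dual-software evidence flag. Annotation comes first because unannotated
ions are never recorded in the reference workflow at all. Both numeric
thresholds are inclusive (≥ 10⁴ mean intensity over biological samples,
zeros included; ≥ 50× sample/blank mean ratio). An ion absent from every
blank has a formally infinite blank ratio and is always retained. The
mean-intensity and blank-ratio stages commute (both are per-feature
predicates on fixed column means), which is asserted on random tables.
The `FilterReport` satisfies conservation — input count = output count +
removals, no id removed twice — and `check_conservation()` enforces it.

## Normalization

Per feature, fit on a training partition: zeros (non-detections) are
imputed with half the minimum positive training intensity, then log₁₀,
then mean-centering and unit-variance scaling with training statistics.
The transform order matters: the log must precede centering (a centered
intensity is negative about half the time). Standard deviations are
floored at 1e-12 so constant features map to 0 instead of NaN. Test
partitions always reuse training parameters; cross-validation refits the
normalizer inside every training fold, so no information leaks from
held-out samples into the transform.

## PLS-DA, VIP, R²/Q², permutation test

PLS-DA is PLS1 regression on ±1-coded labels (benign = −1, the majority
class) via NIPALS with deflation after each component; prediction
thresholds the regression output at 0 with ties resolved to benign. The
implementation is checked against scikit-learn's `PLSRegression`
coefficient path and, for one feature/one component, against univariate
least squares.

VIP_j = √( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ), where SS_a is the y
sum of squares explained by component a; mean squared VIP is identically 1.

R² is the training fit of the full-data model; Q² = 1 − PRESS/SS_tot with
PRESS accumulated from stratified k-fold held-out predictions (default 10
folds). The reported component count maximizes training R² (with the full
per-component curves exposed), which on noise selects the largest model —
exactly the overfitting signature (high R², Q² ≤ 0) the diagnostics are
meant to reveal.

The permutation test uses cross-validated accuracy as its statistic and
the add-one rule p = (1 + #{null ≥ observed}) / (n_perm + 1), which is
exact and cannot return 0. The reference analysis used 2000 permutations;
the test suite and acceptance script use 99–200 to stay desk-scale, which
only coarsens the attainable p-values.

## Supervised autoencoder

Architecture: encoder p → 64 (ReLU) → 2 (linear); decoder mirrors the
encoder; classifier is a linear map from the latent space to 2 logits.
Loss = class-weighted cross-entropy + λ·MSE(x, x̂) with λ = 0.1; Adam at
lr 1e-3, 300 epochs, batch 16, inverse-class-frequency weights for the
unbalanced cohort. Defaults are sized for the 78-samples × 15–3000-ions
regime and are all exposed in `SAEConfig`. Training is a pure function of
(data, config, seed): initialization and batch order come from one
`numpy` generator, so two fits with the same seed are bitwise identical.

The reconstruction term acts as a regularizer: it forces the 2-D latent
space to preserve metabolome-wide structure rather than collapse onto the
decision boundary, which is what makes the latent scatter plot readable
and stabilizes training at n ≪ p. At λ → ∞ classification degrades toward
the majority rate; at λ = 0 the model is a plain MLP classifier (both
asserted in tests).

Per-ion importance is the mean input gradient of the logit difference
(malignant − benign) over training samples, keeping its sign, so an ion
elevated in malignant samples scores positive. This is an
architecture-agnostic saliency, verified against central finite
differences in the tests. Note that gradient saliencies of a trained
network are *not* exactly symmetric under duplicated input columns —
random initialization distributes weight arbitrarily among collinear
inputs — so near-equality of duplicate scores holds only in expectation.

Signature selection is step-by-step top-down elimination: fit, rank by
|score|, keep the top `ceil((1 − drop_fraction)·p)` ions (never fewer
than k), refit, repeat until k remain, then refit once more on exactly k
ions for the reported scores. Halving per round (drop_fraction 0.5) is a
pragmatic schedule — fine enough to protect moderately ranked informative
ions, coarse enough that a 3000-ion table reaches 15 ions in 8 rounds.
Each round derives its own seed from the configured seed, so the whole
cascade is reproducible.

Prediction confidence uses class-conditional Gaussian KDEs of the
predicted malignant probability (Silverman bandwidth per class, floored
at 1e-3; curves renormalized to unit trapezoidal mass on the [0,1] grid).
A sample's confidence is d_own/(d_own + d_other) at its own predicted
probability: 1 where the class densities do not overlap, 0.5 at a
crossing point.

## Evaluation protocol

"k-fold cross-validation" in the reference analysis is implemented here
as repeated stratified Monte-Carlo splitting: each repeat draws
round(test_fraction·n) test samples with class proportions preserved to
within one sample. For a 56/22 cohort at test_fraction 0.25 this yields
test sets of 19–20, matching the per-fold denominators visible in the
published fold tables (e.g. 16/19 = 0.842), which twelve disjoint folds
of 78 could not produce. AUROC is the Mann–Whitney concordance of the
malignant score with ties counted 0.5, computed from average ranks; it
equals trapezoidal ROC integration exactly, ties included.
Precision/recall/F1 are macro-averaged over the two classes. Aggregation
reports the arithmetic mean and the sample (n−1) standard deviation.

The comparison harness freezes the signature before splitting by default,
as the reference analysis did (the 15 ions were selected once on the full
cohort). This overstates generalization: an *honest* mode re-selects the
signature inside every training split via a caller-provided selector, and
on null data its accuracy stays near chance while frozen-signature
evaluation of null-selected ions would not. Both modes are exercised in
the tests.

SVM (linear kernel, C = 1) and random forest (500 trees) come from
scikit-learn behind the same train/predict contract as the SAE and
PLS-DA, with per-split normalization fit on the training partition.

## Synthetic cohorts

The generator emulates the cohort the pipeline assumes, with every fate
planted and bookkept:

- intensities are log-normal: I = 10^(μ_f + δ_class ± ε), with the
  benign/malignant mean ratio split symmetrically in log space between the
  classes; ε has the log-scale SD implied by a biological CV of 0.35
  (≈ 0.15 dex). The reference study reports only mean ratios, no
  dispersions; log-normal with CV ≈ 0.35 is a standard model for LC-MS
  peak areas.
- the 15 informative ions default to the reported benign/malignant ratio
  vector (0.554 … 7.002), thirteen in positive and two in negative mode,
  mirroring the published signature layout.
- decoys: a below-threshold population (base intensity drawn from a zone
  whose sample mean is safely under 10⁴ yet above the detection limit), a
  blank-contaminated population (blank level = sample level / U[2, 20],
  drawn among intensity-passing ions so the contamination itself is
  detectable), and unannotatable ions kept ≥ 25 ppm from every adduct
  mass. Ion positions are rejection-sampled so that any two same-mode
  ions within 30 ppm are ≥ 2 min apart in RT, guaranteeing that the 3 ppm
  / 0.2 min per-run jitter can never merge distinct ions at the 10 ppm /
  1 min join tolerance.
- fate flags (annotatable / survives intensity / survives blank) are
  planted by construction and then verified against the realized
  intensity matrix before the generator returns; the filter-cascade test
  compares cascade counts on the *aligned, round-tripped* table against
  this bookkeeping, so it exercises alignment and filtering end to end.
- `paper_fixture()` is the seed-locked miniature (78 samples, 500 + 200
  ions, 15 informative, seed 7823) used by the tests, the docs and the
  acceptance script; it is regenerated on the fly and is byte-stable.

What passing these tests shows: the pipeline's operations are correct
under the stated statistical model at desk scale. What it does not show:
performance on real FNAC fluids, where ionization drift, correlated ion
clusters (isotopes, in-source fragments), heavier-tailed intensity noise,
batch effects and missingness-not-at-random all exist and are not
simulated. The published clinical metrics therefore enter the acceptance
suite only as aggregation worked examples over the printed fold values,
never as quantities re-derivable from raw data here.

## Problem sizes and numerical choices

The test suite and acceptance script run the 56/22 cohort at 500 + 200
ions (the full-size 5081 + 2609 regime is available through `CohortSpec`
but unnecessary for verifying correctness), 12 seeds for recovery
medians, 50–200 replicates for null calibration, and 99–200 permutations.
Degenerate inputs are handled explicitly: constant features normalize to
0 (SD floor 1e-12), all-zero features raise a validation error naming the
feature, a zero malignant class mean makes the benign/malignant ratio +∞
with a warning, zero-variance probability sets floor the KDE bandwidth at
1e-3, and NIPALS stops early if the residual covariance vanishes.

## Known limitations

- Only [M+H]⁺/[M−H]⁻ adducts; no isotope envelopes, in-source fragments
  or multimers, so annotation is optimistic relative to real data.
- The SAE importance score is one defensible choice (input gradient of
  the logit difference); other saliencies would rank ties differently.
- The run-order-dependent join aligner is a faithful emulation of the
  greedy family of aligners, not a global optimum.
- Monte-Carlo splitting reuses samples across repeats; the mean ± SD it
  reports is not an unbiased variance of a single-split estimator.
- QC runs are generated and carried through tables but no drift
  correction is applied (none is modeled either).
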