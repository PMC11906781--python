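# Methods

## Scope and model

The package implements the chemometric chain used in cell-metabolomics
studies that compare a small number of treatment groups with technical
replicates and pooled QC injections: normalization, exploratory PCA with
removal of a systematic-noise component, supervised classification with
nested validation, feature selection, annotation arithmetic and pathway
over-representation. The group labels default to CTRL, M (treatment),
H2O2 (oxidant) and M+H2O2 (combination), but nothing downstream depends on
their meaning.

## Synthetic data generator

Intensities follow an additive model on the log10 scale,

    log10 x_ij = b_j + d(c_i, j) + t_i v_j + e_ij,     x_ij -> x_ij * k_i

with feature baselines `b_j ~ N(baseline_mean, baseline_sd²)`, class shifts
`d`, a rank-one batch component (`t_i ~ N(0, batch_sd²)` per sample, `v` a
random unit vector over features), residual noise `e_ij ~ N(0, noise_sd²)`
and a per-sample multiplicative dilution factor `k_i ~ U(lo, hi)`.
Exponentiation guarantees strictly positive intensities (log-normal data,
matching the pipeline's log10 step). Informative features are allocated
round-robin to the non-control classes — each treated class gets a
dedicated marker block shifted by ±`effect_size` — so every class is
identifiable and the control is defined by absence of shifts. QC samples
take the baseline profile with batch, noise and dilution but no class
effect, mimicking pooled reference injections. The batch effect is
rank-one because the removal step excises exactly one principal component.

Defaults: 4 classes × 5 biological × 3 technical replicates, 6 QCs, 150
features of which 30 informative, `effect_size` 0.8, `batch_sd` 0.8
(chosen so the artifact dominates a leading PC, the regime the removal
step targets), `noise_sd` 0.1, dilution 0.7–1.3, baselines 5.0 ± 0.8
(log10 counts). The biological replicate count per group is configurable,
not asserted. All randomness derives from one master seed; per-stage
streams are split by hashing stage labels, so any stage is reproducible in
isolation.

What the generator does **not** emulate: retention-time drift, peak
detection or integration errors, heteroscedastic (intensity-dependent)
noise, correlated feature blocks from shared pathways, and missingness
beyond an optional uniform dropout. Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical structure, not
robustness to every artifact of real LC-MS data.

## Normalization

Order is fixed: median-by-row → PQN → log10 → autoscale, each applied once.
The PQN reference is the element-wise median spectrum of the control group
(the spectrum reading; a scalar per-group median is the other possible
reading of the usual wording and is noted here, not implemented). Features
with a zero reference median are excluded from the quotient median with a
warning. Zero intensities are handled by a global offset of half the
smallest non-zero value (`zero_policy="offset"`, the default) or rejected.
Autoscaling uses the sample SD (n−1); this convention slightly changes
loadings versus the population SD and is therefore stated. Columns whose
SD is below `sqrt(eps) · max(|mean|, 1)` are treated as constant and
dropped with a warning. The fitted state (reference spectrum, column
means/SDs, offset, kept-feature mask) reapplies the identical transform to
new samples; row medians and quotient factors are per-sample quantities and
are recomputed, so no statistic of the held-out data enters the model.

## PCA, ellipses, reconstruction

PCA is a singular value decomposition of the preprocessed matrix;
explained fractions are `s_a²/Σs²`. Loading signs follow a deterministic
convention (largest-magnitude element positive) so quadrant calls are
reproducible. Hotelling ellipses use the group's 2×2 score covariance and
critical value `c = 2(n−1)/(n−2) · F(α; 2, n−2)`; other small-sample
scalings exist, and at the Monte-Carlo sizes tested the choice is
indistinguishable. Component removal subtracts only the dropped
score-loading products, keeping residual variance beyond the modelled
components — the minimal intervention consistent with "reconstructing" the
data after excising an artifact. Which component to drop is always an
explicit argument (default: none); `rank_components_by_correlation` ranks
candidates against a nuisance covariate but never drops automatically.
After removal, technical replicates are averaged and the final PCA is
refit **without** re-autoscaling: columns remain near unit scale and
re-scaling would partially reintroduce the removed direction (a
`refit_autoscale` flag restores re-scaling). QC samples are excluded from
the final model by default.

## PLS-DA and validation

PLS-DA is PLS2 regression (NIPALS, via scikit-learn, `scale=False`) on a
centered one-hot indicator matrix; class assignment is the argmax of the
predicted responses with ties broken by class order. The latent-variable
count A is selected in an inner venetian-blinds loop (fold = position mod
folds along a class-stratified ordering), taking the A with minimal mean
CV misclassification and the smallest A on ties. Because NIPALS components
are nested, one fit at the maximal A provides predictions for every
smaller A exactly, which makes the inner loop cheap.

The outer loop splits samples into cancellation groups by dealing each
class's shuffled samples round-robin from a random offset, so per-class
group sizes differ by at most one. This balance matters: with unbalanced
training folds the held-out class is underrepresented and null-data
accuracy drops systematically below chance; with balanced folds the
permuted-label accuracy sits at 1/n_classes as it should. Metrics are
reported as mean ± SD over repetitions (the other reading — SD over outer
folds — is not used). VIP scores are computed per outer model and
summarized as the fraction of models in which a feature exceeds VIP = 1,
the conventional importance threshold. The permutation test reruns a
single-repetition rDCV per shuffled label vector (full repetition stacks
per permutation would multiply cost with no change in calibration) and
uses the +1-corrected empirical p-value, which is unbiased and never zero.

## Annotation arithmetic

Monoisotopic masses use IUPAC/CODATA values (H 1.007825032, C 12 exactly,
N 14.003074005, O 15.994914620, S 31.972071174, P 30.973761998, plus Na,
K, Cl, F). Adduct m/z for singly charged species is
`m·M + δ·1.007276467 − w·18.010565` (multiplicity m ∈ {1,2}, protonation
δ = ±1, water loss w ∈ {0,1}); the electron mass is absorbed into the
proton constant, a difference far below printed precision. Flavylium
cations of anthocyanins are handled through the same [M+H]+ arithmetic on
the neutral-form formula, matching how annotation tables label them. ppm
errors are computed at the ion level; published error columns are only
reproducible to roughly ±0.5 ppm because printed m/z values carry 4–5
decimals, and the bundled-table tests use exactly that tolerance. For
LOD/LOQ the SD entering 3.3·SD/slope and 10·SD/slope is the regression
residual SD by default (`sd_source="intercept"` selects the intercept
standard error instead).

## Pathway over-representation

The p-value is the exact hypergeometric upper tail, evaluated through a
log-space survival function. The universe is an explicit parameter: the
bundled library embeds its five pathways in a configurable background
(default 100 metabolites), and published p-values from online tools are
not comparable because they depend on the tool's library version and
universe. Raw p at α = 0.05 is the default criterion; Benjamini–Hochberg
adjustment is available but off. Topology-based "pathway impact" is
deliberately not implemented; the results table carries a hit-fraction
placeholder column explicitly labelled non-equivalent.

## Problem sizes and numerical choices

The test suite and examples run rDCV at 10 outer × 10 inner groups with
10 repetitions and 99 permutations. Calibration checks use sizes chosen
for Monte-Carlo adequacy: the separability check uses 10 biological
replicates per class (one sample per class per cancellation group), and
the chance-level check 20 per class, where a single permutation's sampling
noise (≈5% SD) is small enough to resolve the expected 25%. Hotelling
coverage is checked at 10⁵ points (±0.5% tolerance). Tolerances of 1e-10
are used for exact linear-algebra identities (projections, round trips)
and 1e-8 for orthonormality.

## Known limitations

- The rank-one batch model cannot represent multi-component or
  class-confounded batch structure; dropping a PC that carries biology
  degrades classification, which is why removal is never automatic.
- PQN assumes the majority of features are not differentially abundant;
  with many informative features the quotient median drifts.
- rDCV sensitivity/specificity SDs are computed over repetitions and
  understate fold-to-fold variability for very small groups.
- The annotation module covers singly charged adducts with at most one
  water loss and dimerization; isotope patterns and MS² matching are out
  of scope.
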