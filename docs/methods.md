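# Methods

## Thermal feature extraction

Each subject contributes two temperature maps (left/right foot, °C) with
angiosome label masks over {background, MPA, LPA, MCA, LCA}. For every foot
and every region (the four angiosomes plus the entire foot) the package
computes:

* **Summary statistics** — mean, population standard deviation, max, min,
  skewness m₃/m₂^1.5 and non-excess kurtosis m₄/m₂². A constant region
  returns skew = kurtosis = 0 by convention so feature vectors stay total.
* **NTR occupancy** — the fraction of region pixels in each of ten fixed
  temperature classes partitioning [18, 37) °C: C1 = [18, 22), C2 = [22, 26),
  C3–C9 at 1 °C steps from 26 °C, C10 = [33, 37). Out-of-range temperatures
  saturate into C1/C10 rather than erroring (the generator clips, but real
  inputs may not). Each class is represented by its classmark, the interval
  midpoint.
* **ET** — the occupancy-weighted mean of the classmarks.
* **ETD** — the unsigned difference of ET between the corresponding regions
  of the two feet. ETD features carry no foot prefix (`Foot_ETD`,
  `MPA_ETD`, …).
* **HSE** — the classmark of the hottest class whose occupancy reaches a
  floor (default 5%); if none does, the hottest occupied class. The floor is
  configurable, and the definition is a documented semantic choice: it reads
  "hot spot" as "the hottest temperature band occupied by a non-negligible
  area".
* **TCI** — the mean absolute deviation of the four angiosome mean
  temperatures from fixed control references (MPA 25.8, LPA 25.7, MCA 26.4,
  LCA 26.1 °C). The reference map is an argument, so alternative control
  populations or formulas can be swapped in.

Names follow `<side>_<region>_<variable>` (`R_LPA_min`, `L_MPA_NTR_C3`),
with the region dropped for whole-foot features (`L_kurtosis`, `R_NTR_C5`)
and the side dropped for ETDs. The schema totals 189 features: 2 feet × 5
regions × (6 statistics + ET + HSE + 10 NTR) + per-foot TCI and highest
temperature + 5 ETDs. The per-foot highest temperature deliberately aliases
the whole-foot max; the correlation pruner removes one of the pair.

## Preprocessing

Feature tables with identical schemas are row-concatenated without any value
transformation (a provenance column records origins). The minority class is
oversampled to parity with SMOTE (k = 5 neighbours): each synthetic row is
x_i + u (x_j − x_i), u ~ U(0, 1), with x_j one of the k nearest minority
neighbours of minority row x_i; originals are preserved verbatim.

Redundancy pruning scores every feature by the AUCROC of a single-feature
logistic model, visits features in descending score (ties by name), and
drops any feature correlated above |r| = 0.95 with an already-kept one.
Visiting best-first makes the procedure deterministic and invariant to
column order; constant features are dropped with a warning since their
Pearson correlation is undefined. Cross-validation uses stratified 5-fold
splits; all model-based stages standardize features with training-fold
statistics, because the L1-logistic model, SMOTE and the SVM are all
scale-sensitive. By default SMOTE and pruning run once on the full table
(folds are built afterwards); the stages are exposed separately so a
stricter inside-the-fold protocol can be composed when leakage control
matters more than matching the single-global-step design.

## Dropout selectors

The classifier is a multilayer perceptron D → 64 → 32 → 2 with ReLU hidden
units, ordinary inverted dropout (rate 0.2) on both hidden layers, and a
softmax head; the feature selector is a stochastic multiplicative gate on
the input layer, one gate per feature. Training uses Adam (β = 0.9/0.999)
for 500 epochs at batch size 32 (a final batch shorter than 4 samples is
merged into the previous one), learning rate 10⁻² for concrete gates and
10⁻³ for variational gates. The regularizer weight λ anneals linearly at
2.5×10⁻³ per epoch and saturates at 1 from epoch 400, so the network can
learn a representation before sparsity pressure applies.

**Variational gates.** The gate weight posterior is N(θ_d, α_d θ_d²),
sampled per example. The loss is the mini-batch evidence-lower-bound
estimator in minimization form, (N/M) Σ_batch NLL + λ·KL, with the
log-uniform-prior KL in Molchanov's approximation
−(k₁σ(k₂ + k₃ log α) − ½ log(1 + α⁻¹) − k₁), k = (0.63576, 1.87320,
1.48695), summed over features. Internally the free parameters are
(θ, log σ²) with σ² = αθ² — the *additive* parametrization w = θ + σε,
identical in law to θ(1 + √α ε). This choice is load-bearing: the KL is a
function of log α = log σ² − log θ², so in the additive form it exerts a
shrinkage force on θ and α can grow without bound for irrelevant features.
Parametrized directly in log α, the KL gradient plateaus near zero above
log α ≈ 2 while the data term's keep-pressure does not, and no gate ever
crosses the drop threshold regardless of initialization — an equilibrium
artifact, not a property of the model. Gates start at θ = 1,
log σ² = −1 (moderate noise); MLP weights use He fan-in initialization.

**Concrete gates.** The drop indicator is relaxed to
d = σ((logit ρ_d + log ε − log(1−ε))/t), ε ~ U(0,1), with temperature
t = 0.1 (fixed; small enough that gates are near-binary, large enough that
gradients flow), and the input is multiplied by the keep gate 1 − d. The
loss is the batch-mean NLL plus λ·(1/D) Σ_d (1 − ρ_d): the per-feature
probability of staying active, i.e. a smooth count of features used. Drop
probabilities start at ρ = 0.1 (gates mostly open).

**Ranking and sparsification.** After training, the effective drop
probability is ρ_d directly (concrete) or α_d/(1+α_d) (variational,
inverting α = ρ/(1−ρ)). Relevance is 1 − ρ_d; the keep mask is
ρ_d ≤ τ with τ = 0.9, boundary-inclusive (only strictly noisier gates
drop). Scores can be averaged over cross-validation folds, with the
ordering recomputed from the mean and ties broken by feature name.

All networks, gradients and the Adam optimizer are plain numpy. The
analytic gate gradients are verified against central finite differences in
the test suite.

### Observed sparse-rate regimes

Sparsification under these losses is driven by data-term saturation: when
the classification task is solved, data gradients vanish and the annealed
regularizer prunes unused gates unopposed. Three regimes follow, all
measured by the acceptance suite:

* Strong sparse signal (10/140 informative, d = 2, 122/class): both
  selectors drop ≈ 0.92 of features and place 8–10 of the 10 informative
  columns in their top-20 in ≥ 9 of 10 seeded runs.
* Half noise (70/140 informative): variational settles near 0.57 sparse.
  Concrete overshoots (≈ 0.9): seventy effect-size-2 columns are highly
  redundant, so the saturated likelihood releases surplus informative
  features to the penalty. Real thermogram features are individually weaker
  and mutually correlated, which the independent-column generator
  deliberately does not emulate; the overshoot is a property of the
  benchmark's redundancy, not of the selector.
* Zero signal: neither selector collapses within 500 epochs (sparse ≈ 0.0
  and ≈ 0.13). With nothing to classify the task is never solved; the
  network partially memorizes the training sample, and that residual
  first-order keep-pressure outweighs the bounded per-feature regularizer
  gradient under Adam's normalization. High sparsity on uninformative
  inputs should therefore *not* be expected from this protocol; rankings
  (which need only the relative ordering of gate noise) remain meaningful.

## Baseline rankers, coincidence, evaluation

LASSO rankings are |coefficients| of an L1-penalized logistic model with the
penalty chosen per training fold by internal cross-validation, averaged over
folds; the mask marks nonzero averaged coefficients. Random-forest rankings
average impurity importances over folds (500 trees; hyperparameters are
scikit-learn defaults); as a dense method its mask is the configurable
top-k. Both emit the same RankingResult contract as the dropout selectors.

The coincidence rule intersects the top-30 of every supplied ranking,
assigns each surviving feature its best (minimum) rank across methods,
discards final ranks ≥ 50, and reports the rest in ascending final rank
(ties by name) with rank-interval buckets (<10, <20, <30, <50). "Best rank"
is read as numerically smallest, consistent with the bucket containing the
overall best feature.

Feature subsets are scored by an RBF-SVM with frozen hyperparameters
γ = 0.1, C = 1 over stratified 5-fold CV, features standardized per
training fold. Metrics are binary with diabetic as the positive class
(precision/recall/F1 are therefore driven by the diabetic samples);
means ± SD are across the five folds. A randomized log-uniform search
(γ ∈ 10^[−4,1], C ∈ 10^[−2,2], 200 draws from one seeded stream, so more
draws can never do worse) provides the optimized-reference configuration.
For comparison against prior work, a ten-feature reference list is
provided; its NTR classes are remapped by temperature range onto this
schema (the two remaps fixed by the prior work's ranges, NTR_C4→NTR_C8 and
NTR_C3→NTR_C7, extended by the same +4 offset to NTR_C2→NTR_C6 and
NTR_C1→NTR_C5) and each entry resolves to the mean of the left- and
right-foot columns, since the prior work did not separate feet.

## Synthetic data

The thermogram generator emulates only what the downstream mathematics
touches. Feet are elliptical silhouettes; angiosomes are proportional cuts
(the plantar/calcaneal boundary at 60% of foot height, the medial/lateral
boundary at half the foot width, mirrored between sides) — real anatomical
contours are irrelevant to region-wise statistics. Each subject draws one
foot-mean temperature from its class law (diabetic N(30.2, 1.3²) °C,
healthy N(26.8, 1.8²) °C); within-foot texture is smoothed white noise with
0.8 °C amplitude, re-centred so the foot mean is exact; diabetic feet add
0–3 Gaussian hot spots of +1.5 to +3 °C (uniform count per foot), which
create class-discriminative HSE/NTR/ETD structure without biasing TCI
alone. All temperatures clip into [18, 37) — clipping rather than
resampling keeps the generator total. The tabular generator emits
independent Gaussian columns with a chosen number of informative columns
mean-shifted by a chosen effect size (in SD units) in one class.

What passing tests show — and do not show: the generators provide exact
ground truth for recovery and calibration checks, but they have independent
features, no camera noise or vignetting, no segmentation error, and no
within-class physiological heterogeneity beyond the mean law. Performance
numbers on them bound what the machinery can do under ideal conditions;
they say nothing quantitative about real thermogram cohorts.

## Numerical choices and degenerate inputs

* Population (ddof 0) moments everywhere in feature extraction; constant
  regions return skew = kurtosis = 0.
* NTR occupancy must sum to 1 within 1e-9 before ET is computed.
* log α is clipped to ±10 inside KL evaluation and θ² is floored at 1e-10
  in the α = σ²/θ² inversion; softmax logits are max-shifted.
* Ties in every ordering (pruning, rankings, coincidence) break
  lexicographically by feature name, making all outputs deterministic
  functions of the seed.
* Degenerate geometry (an empty angiosome), empty regions, NaN
  temperatures, single-class folds, non-finite losses and mismatched
  feature sets all raise immediately with the offending item named.

## Limitations

* The TCI and HSE formulas are semantic reconstructions (deviation from
  control means; hottest meaningfully-occupied class) with strategy hooks,
  not transcriptions of a published formula.
* The 189-feature schema is a documented constant of this implementation;
  other reasonable enumerations of the same feature families yield counts
  in the 180–200 range.
* Sparse *rates* from the dropout selectors are regime-dependent (see
  above); treat the ranking as the primary output and the mask as a
  thresholded view of it.
* SMOTE and pruning applied once globally (the default) leak information
  across CV folds; use the per-fold composition for unbiased error
  estimates on real data.
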