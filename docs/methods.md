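# Methods

This note records the models, parameter choices and numerical conventions
behind `keyfeat`, and what the synthetic experiments do and do not show.

## Scoring model

The package's statistical core is a bag-of-features model over two
magnifications.

**Step 1.** Low-magnification 128-px patches are encoded by a patch
autoencoder and clustered with k-means into K features. For patch *j* of
slide *i*, the one-hot assignment is
u_{i,j,k} = 1 iff k = argmin_k d_{i,j,k} (Euclidean distance to centroid
k; ties go to the smallest index). With n_pos and n_neg the total patch
counts of the recurrence and non-recurrence groups, the degrees are
r_pos,k = Σ₊ u_{i,j,k}/n_pos and r_neg,k = Σ₋ u_{i,j,k}/n_neg, and the
impact score is I_k = r_pos,k/(r_pos,k + r_neg,k). When both degrees are
zero the ratio is 0/0; the score is stored as missing (NaN), never as
0.5, and such features are excluded from counting. Patch scores are
I_{i,j} = Σ_k I_k u_{i,j,k}. Group totals n_pos/n_neg count all patches of
a group, so after background removal the degree sums equal the retained
fraction rather than 1.

**Background removal** is cluster-level: a feature is flagged when its
member patches average at least 240/255 brightness with mean saturation
at most 0.05. Flagged features carry no impact score and always count 0.

**Step 2.** Every 1024-px high-magnification region behind a retained
grid cell is cut into 28-px sub-patches (36 × 36 = 1296 per region; 1024 =
36·28 + 16, so a 16-px right/bottom margin is discarded). Sub-patches are
scored winner-take-all over the second autoencoder's bottleneck units,
u′ = 1 at argmax_{k'} v′ (ties to the smallest unit). Unit degrees mirror
Step 1 at unit granularity and the region score I′_{i,j} is the mean unit
impact over the m sub-patches used.

Raw bottleneck activations carry per-unit scale offsets — without
correction a single high-baseline unit wins the argmax for every input —
so the pipeline standardises each unit (z-score, moments estimated on the
key-feature sub-patches) before the winner-take-all step. The score then
reflects which unit responds most strongly *for that sub-patch* relative
to its typical level. The standardisation is label-free and monotone per
unit.

**Step 3.** A score above 0.5 is a positive character, below 0.5
negative; exactly 0.5 or missing is a tie. Patches are retained only when
both characters are defined and agree. Retained patches are tallied per
feature and slide (raw counts, not area-normalised); patient vectors are
slide means multiplied elementwise by w_k = 1 + |I_k − 0.5| ∈ [1, 1.5]
(w = 1 for undefined I_k). Averaging before weighting is mathematically
equivalent to the reverse order.

## Autoencoders

No deep-learning framework is used: the autoencoder is plain numpy with
manual backpropagation, which keeps training single-threaded and exactly
reproducible under a seed. The architecture is a stack of non-overlapping
block convolutions (kernel size = stride — a shared linear map per image
block) with leaky-ReLU (α = 0.1), a fully connected softplus bottleneck of
exactly `code_dim` units, and a mirrored decoder ending in a sigmoid over
RGB in [0, 1]; the loss is mean squared reconstruction error under Adam.
Two activation choices matter at short training budgets: plain ReLU
bottlenecks die irrecoverably while the decoder bias captures the mean
image (softplus has no dead zone and stays positive, so unit argmax is
meaningful), and leaky hidden units keep gradients flowing everywhere.

Full-scale defaults follow the two bottleneck widths the method is built
around: 2048 units for 128-px patches and 1568 for 28-px sub-patches.
Desk-scale synthetic runs use reduced widths (128 and 48) with one block
stage each ((16 px, 16 ch) and (7 px, 12 ch)), 5 epochs, batch 64, and
learning rates 3·10⁻³ (low) / 10⁻³ (high); downstream mathematics depends
only on the code width. Whether activations should be taken pre- or
post-nonlinearity is genuinely open; the package uses post-nonlinearity
values, consistent with the non-negativity required by argmax scoring.

## Clustering and prediction

k-means uses Euclidean distance on the raw codes (no standardisation by
default; both are configurable) with 10 seeded restarts. K defaults to
100 — the feature count the method is designed around — while synthetic
runs use K = 20, comfortably above the number of latent texture classes;
multiple clusters per morphology are expected and harmless since each
inherits a consistent impact score.

Key features are fitted on a **balanced key-feature subset**: all
positive patients plus an equal-size seeded draw of negatives. This
mirrors the design of the emulated study, whose feature-generation slide
set was balanced by construction, and prevents cluster allocation from
being driven by outcome prevalence. Autoencoder training, clustering,
background flagging and both impact profiles use only this subset; every
slide is then assigned, scored and counted. At desk scale the prediction
stage cross-validates over *all* analysis patients, including the key
subset — with only 200 patients a held-out split would leave the feature
stage without positives. This overlap slightly flatters absolute AUCs and
is the main caveat on the synthetic prediction numbers; the permutation
null (below) shows the pipeline itself does not manufacture signal.

Models: lasso and ridge are L1/L2-penalised logistic regressions
(liblinear) on standardised features with C chosen on a 7-point log grid;
the SVM is RBF with C and γ tuned; the grade model is unpenalised
logistic regression on the numeric ISUP grade group 1–5 (one-hot coding
available); combined models append the grade as one extra column.
Hyperparameters are chosen by inner cross-validation (5-fold, stratified)
on the outer training folds only. The outer loop is stratified 10-fold
(inferred from the fold bookkeeping the method reports: exactly 4
positives per fold at 40/742 is only possible under stratification);
reported AUC is the fold mean with a 95% CI from fold-level variance.
External validation fits once on the training cohort and uses the
Hanley–McNeil rank-statistic variance for the CI. Pseudo-R² is Nagelkerke
on a univariate logistic refit of outcome on the model score with a
likelihood-ratio p-value — defined this way it applies uniformly to all
scorers, including the SVM, which has no native likelihood. Labels at a
horizon: 1 if recurrence ≤ horizon, 0 if followed at least to the horizon
without recurrence, censored otherwise.

## Synthetic data

The generator emulates the statistical structure the pipeline consumes,
not histology. Slides are mosaics of 1024-px regions drawn i.i.d. from
one of six texture classes (sinusoidal stripes, smoothed Gaussian random
fields, random dots; H&E-like palette), with a white border band
(RGB ≥ 245) occupying ≈ 30% of the area. The low-magnification image is
the exact 8× block mean of the high-magnification slide, so 128-px low
patches correspond bit-consistently to 1024-px regions (the two
magnifications differ by a linear factor of 8, as 25× vs 200×). Texture
frequencies are chosen so each pattern's correlation length is short
relative to a patch; this is the generator's separability contract —
codes must reflect texture statistics, not the layout of individual
pattern instances, or clustering fragments on instance identity.

Default study conditions: class-frequency vectors (0.36, 0.06, 0.145 × 4)
for recurring patients and (0.06, 0.36, 0.145 × 4) for non-recurring, so
exactly two classes are discriminative (true enrichments 0.857 and 0.143;
the four shared classes sit at 0.5); prevalence 0.25 (a realistic
mid-term biochemical recurrence fraction, which also gives the balanced
key-feature subset about half the cohort, the same regime as the study's
feature-generation group); one slide of 3 × 3 regions per patient; a
log-normal PSA-like covariate (log-mean 3.1 vs 2.35, log-sd 0.65);
grade-group distributions skewed upward in recurring patients; recurrence
times uniform in (0, 12] months for positives and follow-up of at least
the horizon for negatives. The default roster of 1007 patients carries
exclusion flags (115 neoadjuvant, 7 adjuvant, 43 lost to follow-up) so
the cascade leaves 842 for analysis; an external-style roster of 102 with
(1, 1, 5) leaves 95.

Rendering details chosen for speed without changing the statistics:
pattern fields are computed at quarter resolution and upsampled; pixel
noise is uniform with matched standard deviation; all randomness derives
from `numpy` seed sequences keyed by (cohort seed, patient, slide,
region), so any region can be re-rendered independently and the streaming
path is bit-identical to assembled slides.

What passing tests show: the pipeline recovers the ranking of true class
enrichments from raw pixels (3-seed mean Spearman ≳ 0.86 at n = 200) and
separates patients (lasso CV AUC ≳ 0.95), and both collapse toward
chance when outcomes are permuted. What they do not show: performance on
real tissue, where morphology is continuous rather than categorical,
staining varies, class frequencies are far less separated, and the
headline accuracies of the original study cannot be reproduced without
its images.

## Numerical conventions and edge cases

- Coordinates are 0-based, half-open, row-major; residual tiling margins
  are discarded, never padded (forced by 1296 = 36² per region).
- Argmin/argmax ties break toward the smallest index (determinism).
- Scores exactly 0.5 are ties and are never retained or shaded.
- Undefined impact (0/0) is missing, excluded from counting, weighted 1.
- The AUC is the tie-averaged rank statistic; constant scores evaluate to
  0.5 with a warning.
- Cross-validation requires at least one patient of each class per fold;
  the inner search shrinks its fold count to the rarer class size and
  falls back to a fixed mid-grid hyperparameter when search is impossible.
- Overlay rendering defaults: opacity 0.35, configurable downscale;
  sidecar TSVs round-trip the overlay losslessly.

## Known limitations

- Synthetic textures are categorical and color-separable; real
  morphological variation is continuous and stain-confounded.
- The desk-scale pipeline samples 16 of 1296 sub-patches per region for
  Step 2 (configurable); full-scale runs should score all of them.
- The key-feature subset is not held out from prediction at n = 200 (see
  above).
- The permutation null retains the original key-subset membership, so it
  tests label independence of the scoring chain, not of subset selection.
- Fold-negative counts under equal-size stratified folds have a smaller
  dispersion than the bookkeeping reported for the original analysis
  (0.42 vs 0.632 at 742/40); only the means are treated as contractual.
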