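# Methods

## The procedure

`nocilabel` operationalizes pharmacological subtype labeling for MEA
single-unit recordings as a two-stage procedure: an unsupervised,
density-based responder labeling rule, followed by supervised prediction of
that label from baseline activity alone.

### Response metric

Each unit's recording is split at the treatment time into a baseline and a
treatment window (default 300 s each, half-open `[t0, t1)` / `[t1, t2)`; a
spike exactly at treatment time belongs to the treatment window). Both
windows are parsed into consecutive 30-s bins (trailing partial bins are
dropped, never rescaled, so max-count comparisons stay on equal-width
bins). The response is the **absolute** max-bin MFR difference
ΔMFR = (max treatment-bin count − max baseline-bin count) / 30 s, in Hz,
with sign preserved. Max-bin ties are broken by the earliest bin. An
absolute (not percent) change is used because percent change degenerates
for near-quiescent units and has lower power on correlated data; this is a
deliberate scope decision — relative-change metrics are not provided.

### Labeling rule

The untreated arm, recorded with the same layout but no compound, yields a
*pseudo-treatment* ΔMFR sample: the natural transience of max-bin
differences. A Gaussian KDE

  f̂_h(x) = (1/(n·h)) Σ_{i=1..n} φ((x − x_i)/h)

is fitted on the pooled untreated values (pooling across wells; the null is
a culture-level property). The bandwidth is Silverman's robust
rule-of-thumb h = 0.9·min(SD, IQR/1.349)·n^(−1/5), with the sample (n−1)
SD. A zero IQR (heavily tied, discrete ΔMFR values are lattice-valued at
1/30 Hz) falls back to the SD; zero spread overall is a hard error — the
caller must never silently substitute a bandwidth.

Every treated and untreated unit is scored under f̂. The threshold is the
10th (linear-interpolation) percentile of the **untreated** units' own
density scores; a treated unit is labeled a presumptive nociceptor iff its
density is strictly below the threshold. Because the density criterion
alone is two-sided (a strongly silenced unit is also a low-density
outlier), and the labeling stimulus is an agonist, the default adds a
positive-ΔMFR constraint; `require_positive_delta=False` restores the
literal density-only rule.

Calibration note: self-applying the two-sided rule to the untreated set
labels ≈10% of units by construction, up to percentile interpolation and
the ties induced by the 1/30-Hz ΔMFR lattice. At the default scale
(~620 units) the measured fraction stays within about one percentage point
of nominal.

### Baseline features

Computed over the *entire* baseline window (never the 30-s response bins,
which would leak the labeling signal into the phenotype):

* **MFR** — spike count / window length (Hz).
* **ISICV** — SD/mean of consecutive ISIs, sample (n−1) SD (configurable);
  requires ≥3 spikes. 0 for clock-like firing, ≈1 for Poisson firing.
* **Pairwise spike synchronization** — the adaptive-coincidence measure:
  each spike is matched to its nearest counterpart in the other train; the
  coincidence window τ is half the minimum of the four adjacent ISIs (own
  preceding/following and counterpart's preceding/following); a spike is
  coincident iff its nearest counterpart lies strictly within τ; the pair's
  value is the mean indicator over all spikes of both trains. At train
  boundaries the distance to the window edge serves as the surrogate
  adjacent ISI (auxiliary-spike convention). The measure is symmetric,
  bounded in [0, 1], and parameter-free. Each unit's **sync_median** and
  **sync_skewness** summarize its pairwise values against every other
  active unit in the same well (pairs never cross wells); the skewness
  estimator is the adjusted Fisher–Pearson G1, with the zero-variance
  convention G1 = 0.

Units failing a precondition (<3 spikes, <3 valid pairs) are excluded and
reported with a reason — never imputed, since silent zeros would distort
the subtype contrasts.

A caution discovered during development: the adaptive-coincidence measure
is **not** monotone under spike insertion. Adding a spike to train A
exactly on an unmatched spike of B always makes that pair of spikes
coincident, but the insertion shrinks the adjacent ISIs — and hence the
coincidence windows — of its neighbours, so the pair-level value can
decrease. Only the local property is asserted in the tests.

### Classifiers

The core learner is a **RUS-boosted decision-tree ensemble** implemented
here from first principles (`RusBoostClassifier`): per boosting round, the
majority class is randomly under-sampled to a 1:1 ratio with the minority;
a depth-limited CART tree is fitted on the resample with the current
boosting weights; the weighted error ε is evaluated on the **full**
training set; the learner weight is α = lr·ln((1−ε)/ε); example weights
are multiplied by e^α on errors and renormalized. Rounds with ε ≥ 0.5 are
discarded and resampled (10 retries, then boosting stops). Scores are the
α-weighted mean of tree class-1 probabilities, in [0, 1]. Feature
importances aggregate per-tree impurity decrease weighted by α.

Reference models — logistic regression, LDA, a k-NN random-subspace
ensemble, and a small feed-forward-network ensemble — delegate to
scikit-learn behind the module surface; the minority class is upweighted
(inverse-prevalence class weights for LOG, uniform priors for LDA,
minority oversampling to parity for the network ensemble, which has no
sample-weight support). Scale-sensitive families standardize features
inside their pipelines.

Model comparison uses stratified 10-fold CV AUC-ROC per model and a
Kruskal–Wallis test over the per-fold values (α = 0.05; "no model
outperforms" when p ≥ α). Hyperparameter search is a seeded, budget-limited
random search over documented per-family spaces (tree depth 1–8, rounds
50–500, learning rate 0.01–1; k ∈ 1–25, subspace dimension 2–3; hidden
sizes 4–64; budget 30), flagged `method="random-search"` in its output;
tuning is done once on the training partition, not nested inside the CV
(flagged as non-nested). Final evaluation holds out whole wells (default
two): within-well correlation (shared network activity) would otherwise
leak across the split. Metrics at the 0.5 score threshold: confusion
matrix, accuracy, per-class F1, AUC-ROC (concordance with ties counted ½),
a confidence–retention curve (confidence = max(score, 1−score)), and a
2-D PCA projection (standardized on the training set, training loadings
applied to the test set). The holdout is evaluated both as-is and on a
seeded class-balanced subsample.

## The synthetic study generator

No public recordings exist for this assay, so `synthetic_mea` generates
studies with known ground truth and the statistical structure the analysis
assumes:

* **Spike trains** are ordinary gamma-renewal processes — ISIs ~
  Gamma(k, 1/(k·λ)), so the rate is λ and the ISI CV is 1/√k — giving
  direct control of MFR and ISICV per subtype.
* **Within-well synchrony** uses the mother-process (single interaction
  process) construction: one Poisson mother train per well (1.2 Hz);
  each unit copies mother spikes with probability p, jittered by a 5-ms
  Gaussian, merged with an independent renewal component whose rate is set
  so the unit's total expected rate is preserved.
* **Treatment response**: in the treated arm, planted responders multiply
  their total rate by `response_gain` (default 4) from the treatment time
  plus a uniform 0–5 s onset latency (droplet-diffusion delay). Untreated
  sessions draw the same subtype mixture (so the pseudo-treatment null
  matches the treated baseline marginal) but apply no rate change and
  carry only non-responder ground truth.

Default scale: 14 wells per arm, 30–60 units per well (~620 units per arm,
the scale of a one-plate agonist study), responder fraction 0.3682.
Subtype parameters: responders — log-normal rate median 1.8 Hz (SD of
log 0.3), shape k = 0.4, mother-copy probability 0.9; non-responders —
median 0.7 Hz (SD of log 0.8), k = 2.0, copy probability 0.2, with 10% of
units drawn at 0.6 (sparse high-synchrony participation). These values
were chosen so that ground-truth responders exceed non-responders in
baseline MFR, ISICV and median pairwise synchrony — the qualitative
subtype structure reported for capsaicin-labeled cultures — with
comfortable Mann–Whitney significance at ~150 units/group.

**What the generator does not emulate.** Real recordings have bursting and
network-burst dynamics, non-stationary baseline drift, electrode-level
unit loss, spike-sorting contamination, and dose-dependent partial
responses; units here are stationary renewal processes with a step-rate
response. One structural mismatch is documented rather than hidden: in
real cultures the non-responder pairwise-synchrony distributions skew
*right* (mostly unsynchronized pairs, few synchronized ones). Under the
adaptive-coincidence measure, the chance-level synchrony of independent
trains is substantial (~0.3) and rate-mismatched pairs fall *below* it, so
with heterogeneous non-responder rates the left tail dominates and their
skewness comes out negative. The skewness feature still separates the
subtypes strongly — but with the opposite sign convention to real data.
Passing tests therefore demonstrate that the pipeline recovers planted
structure of the assumed form, not that it handles every pathology of real
MEA data.

## Numerical choices and problem sizes

* ΔMFR values are lattice-valued (counts/30 s); percentile thresholds use
  linear interpolation and strict `<` comparison.
* KDE evaluation is exact direct summation (vectorized), not a binned or
  FFT approximation; n ≈ 600 reference points makes this trivial.
* Nearest-counterpart search in the synchronization measure is
  `searchsorted`-based; equidistant counterparts resolve to the earlier
  spike (consistent with the brute-force definition used as test oracle).
* Mann–Whitney: exact null for min(n) ≤ 8 without ties, tie-corrected
  normal approximation with continuity correction otherwise; two-sided by
  default; no multiple-testing correction across the four features (a Holm
  option exists, off by default).
* The default test suite and the acceptance script run studies at the
  default scale (~620 units/arm, 600 s sessions) and train 150-round
  depth-3 ensembles — a few seconds end-to-end; CV and tuning scale
  linearly in rounds × folds × budget.
* All randomness flows from one master seed (`SeedSequence`-derived
  per-stage sub-seeds, logged in the run manifest).

## Known limitations

* Binary subtype only; a second nociceptor form or finer subtype taxonomies
  are out of scope.
* The labeling rule is threshold-based on a single scalar response; partial
  or purely temporal (rate-pattern) responses are invisible to it.
* Chance-level synchrony of the adaptive-coincidence measure depends on
  rate similarity and regularity, so sync features mix planted correlation
  with rate structure; this is a property of the measure, not a bug.
* Hyperparameter search is random (seeded), not model-based; with a
  4-feature space and small spaces this is adequate but not optimal.
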