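# Methods

## The estimation problem

Cuff-less, continuous blood pressure estimation infers systolic and
diastolic pressure (SBP/DBP, mmHg) from non-invasive waveforms. The
physiological basis is pulse wave velocity: a stiffer arterial wall
propagates the pressure pulse faster (Moens–Korteweg relation,
`PWV = sqrt(E h / (rho d))`), so the transit time of the pulse from the
heart to a peripheral site falls as pressure rises. This package never
fits the wall-elasticity physics; it uses the relation only as motivation
for the feature set:

* **PTT** (pulse transit time, s) — interval from the ECG R-peak to the
  peak of the second derivative of the PPG (SDPPG) in the same cardiac
  cycle. The SDPPG landmark sharpens the PPG onset.
* **PIR** (PPG intensity ratio) — ratio of the PPG pulse maximum IH to
  minimum IL in the cycle; tracks arterial diameter change. Convention
  here is IH/IL ≥ 1; the literature also uses the reciprocal, so the
  extractor exposes `invert_pir`.
* **HR** (heart rate, bpm) — `60·fs / (R–R interval in samples)`.

Reference targets come from the invasive ABP channel: per cycle,
SBP = max(ABP), DBP = min(ABP).

## The clustered estimator

Per-cycle features are standardized (z-score, population SD) and
partitioned by k-means (Lloyd, k-means++ seeding, `n_init=10`,
`max_iter=300`, `tol=1e-4`); the number of clusters is the argmax of the
mean silhouette score over k = 2..10 (ties to the smaller k). Clustering
uses only the independent variables (PTT, PIR, HR), never the targets.
One regressor pair (SBP model, DBP model) is trained per cluster;
prediction routes each sample to the Euclidean-nearest centroid in scaled
space (ties to the lowest index) and applies that cluster's pair.
Clusters with fewer than `min_cluster_rows` (default 10) training samples
fall back to a single global pair, with a warning.

Totals aggregate per-cluster metrics by the **weighted arithmetic mean**
Σ nᵢvᵢ / Σ nᵢ with cluster sample counts as weights. For MAE this equals
the pooled mean; for RMSE and Pearson r it does not, so the report also
carries `total_rmse_pooled` computed from all squared errors. Total r is
the weighted mean of per-cluster r (clusters with a constant vector have
undefined r and are excluded from that mean).

Three interchangeable learner families are supported, delegated to
scikit-learn: gradient boosting (300 stages, depth 3, learning rate 0.1),
random forest (300 trees, unlimited depth) and a multilayer perceptron
(hidden layers 64/32, ReLU, 500 epochs, Adam, batch 32, with input and
target standardization inside the estimator). Batch 32 rather than
scikit-learn's `min(200, n)` keeps the number of gradient updates per
epoch meaningful for small per-cluster training sets. All estimators are
deterministic given a seed.

The train/test protocol is a random 80/20 split stratified by cluster
label, fixed seed. Clustering is fit on the full feature table before the
split (it uses no target information); reports are produced for both the
held-out and training split, labelled.

## Device-standard grading

* **BHS**: cumulative percentages of absolute errors within 5/10/15 mmHg;
  grade A requires ≥ 60/85/95 %, B ≥ 50/75/90 %, C ≥ 40/65/85 %, else D;
  all three thresholds of a grade must hold. Closed bounds (≤) are used on
  both error and percentage, following the standard's tabulated column
  heads.
* **AAMI**: pass iff |mean error| ≤ 5 mmHg, error SD ≤ 8 mmHg and at
  least 85 subjects. The subject count cannot be derived from cycle-level
  data, so it is an explicit input (defaulting to the row count, i.e.
  cycle-level grading, when not supplied).
* **Bland–Altman**: bias = mean(estimate − reference) and limits of
  agreement bias ± 1.96·SD (sample SD, ddof = 1).

## The synthetic population

Real multi-patient waveform corpora are large, access-restricted
downloads; the package therefore ships a generator whose records are
exact by construction, so extraction accuracy can be tested against known
truth rather than against another detector.

Each beat window of `round(fs·60/HR)` samples contains:

* an ECG Gaussian spike (σ = 8 ms) whose maximum lies exactly on the
  window's first sample (the R-peak); a 0.3 s baseline lead-in prevents
  edge truncation of the first beat;
* a PPG pulse built by double-integrating a designed curvature profile —
  a positive Gaussian curvature bump centred exactly at
  `round(PTT·fs)` samples after the R-peak, a negative bump at the
  systolic peak, and a weaker positive bump at the end of the decay.
  Because the rise is steeper than the decay, the onset bump dominates
  the SDPPG, and because a symmetric smoothing kernel preserves the peak
  of a symmetric bump, the extracted PTT equals the drawn PTT to within
  half a sample. (A subtlety: the discrete second central difference of a
  double cumulative sum evaluates the curvature one sample late, so the
  kernels are placed at `onset + 1`.) The pulse is affinely normalized so
  max/min realize the drawn PIR exactly;
* an ABP pulse from the same template normalized to the drawn SBP/DBP.

Truth rows record the drawn values; if a drawn PTT cannot fit its beat
window (pathologically fast rhythms), the onset is clamped and the truth
row follows the waveform.

### The default five-regime population

The clustering step only pays off on *multitrend* data — feature clouds
with distinct centres **and** distinct pressure responses. The default
population (`default_regimes()`) encodes that structure explicitly:

* five regimes in (PTT, PIR, HR) space at ≥ 5.3 within-regime-SD minimum
  pairwise separation, arranged obliquely so that no single feature
  separates them (every 1-D projection interleaves);
* within-regime SDs: PTT 0.012 s, PIR 0.07, HR 3 bpm around a base point
  of (0.22 s, 2.0, 85 bpm);
* regime-specific responses `BP = intercept + c_inv/PTT + c_pir·PIR +
  c_hr·HR + noise`, with coefficient signs alternating between regimes
  and magnitudes normalized so the three terms contribute ~11/8/7 mmHg of
  within-regime SBP signal SD (DBP 0.9× that); additive pressure noise SD
  3 mmHg;
* regime mean pressures assigned so that regimes *adjacent in feature
  space* differ strongly (SBP means 135/90/185/175/100, DBP
  80/48/118/110/55 mmHg — ICU-like spread);
* 400 beats per regime by default (the extraction-closure checks use 200,
  which keeps the noise-free waveform runs fast).

This geometry is what makes the clustered-versus-global comparison
meaningful: a global model must represent five differently-sloped,
strongly offset response surfaces at once and blurs across the oblique
regime boundaries, while per-cluster models each fit one smooth surface.
With axis-separable regimes or near-identical responses, all three global
learners match the clustered ensemble and the comparison degenerates.

### What the generator does not emulate

Motion artifacts, baseline wander, arrhythmia, beat-morphology
variability, sensor noise on ECG/PPG, and intra-patient drift. Passing
closure tests therefore demonstrates correctness of the landmark
arithmetic and the pipeline plumbing, not robustness to clinical signal
quality. Likewise the cluster-gain property shows the method behaves as
designed on data with the assumed structure; it is not evidence about any
particular clinical corpus.

## Numerical choices and degenerate inputs

* Beat windows are half-open `[r_i, r_{i+1})`, 0-based; one feature row
  per window, all five quantities from the same window; cycles failing
  any gate (PTT outside 0.05–0.6 s, HR outside 30–220 bpm, PPG minimum
  ≤ 0, SBP < DBP) are dropped and counted.
* The R-peak detector is a derivative-energy detector (detrend by 0.6 s
  moving mean, squared gradient, 0.12 s integration window, adaptive
  threshold `max(0.2·peak, 4·median)`, 0.25 s refractory), with candidate
  peaks refined to the local raw-ECG maximum. A flat or empty signal
  yields an empty annotation, not an exception.
* SDPPG is the second central difference scaled by fs², after an optional
  moving-average smoothing (default 40 ms, forced to an odd sample count
  so landmark positions are unbiased); edges replicate the nearest
  interior value.
* Silhouette convention: singleton clusters contribute 0; identical
  points split across clusters score 0 (a = b = 0).
* A constant feature column gets scale 1 (with a warning) rather than a
  division by zero.
* Empty-cluster handling inside k-means follows scikit-learn's
  relocation rule; the model constructor rejects any fit that would leave
  a cluster empty.
* CSV round-trips use 17-significant-digit formatting and
  correctly-rounded float parsing, so write→read is the identity on
  finite values.

## Known limitations

* The MLP family has the weakest margin in the clustered-versus-global
  comparison: a well-converged global MLP interpolates oblique smooth
  structure effectively, so on rare seeds it edges out the per-cluster
  ensemble on one target.
* Cycle-level AAMI grading is not subject-level grading; the subject
  count input exists precisely because the mapping from cycles to
  subjects is corpus-specific.
* Per-cluster Pearson r is undefined for constant clusters and such
  clusters are silently excluded from the weighted total r.
* The pipeline clusters before splitting (stratification requires it);
  for strict out-of-sample claims about the *clustering*, refit on the
  training split only.
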