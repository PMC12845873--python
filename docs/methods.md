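# Methods

This note records the modeling choices behind `eegfuse`, the parameters
that matter, and what the synthetic benchmark does and does not show.

## Synthetic EEG generator

The generator emulates a 17-channel, 250 Hz resting-state recording in
which the scalp topography is piecewise-stable:

- **State dynamics.** A semi-Markov chain over K = 4 classes. Segment
  classes follow a row-stochastic transition matrix with zero diagonal;
  segment lengths are gamma-distributed with shape 2 (fixed coefficient
  of variation ≈ 0.71) and a per-class mean, default 80 ms — the
  conventional microstate time scale. Shape 2 keeps sub-sample segments
  rare while still producing a realistic spread of durations.
- **Topographies.** Four zero-mean, unit-norm channel vectors, drawn
  once per cohort (QR-orthogonalized Gaussian vectors, pairwise |r| ≈ 0)
  and shared by all subjects, as microstate topographies are in real
  cohorts.
- **Carrier.** The active template is multiplied by a rectified 10 Hz
  sinusoid, mimicking the alpha-band oscillation that dominates resting
  EEG and making GFP peak twice per cycle.
- **Noise.** An equal-power mix of spatially white Gaussian noise and
  per-channel 1/f-amplitude noise, scaled so that template-signal power
  over noise power equals `snr` (default 4).
- **Drift.** A 0.15–0.9 Hz band-limited per-channel wander scaled by
  `drift_amplitude` (in units of signal RMS, default 0.2). The band sits
  above the 0.1 Hz preprocessing high-pass so the nonstationarity
  survives filtering and is expressed in the low-frequency IMFs.

**Planted group contrasts** (the two-group study conditions): the patient
group has class-A mean duration 110 ms vs 80 ms, B→D transition
probability 0.6 vs 1/3, and drift amplitude 1.0 vs 0.2. The first two
make microstate features informative; the third separates the groups in
EMD statistics (variance/SD/RMS of slow IMFs). A three-group variant
scales the same contrasts (severe > mild > control), and a null variant
uses identical parameters for both groups. The benchmark cohort is
2 × 16 subjects × 60 s; one-subject recovery checks use 5 minutes. These
sizes are the package's benchmark conditions; real studies use more
subjects and 15-minute recordings.

What the generator does **not** emulate: biophysical forward modeling and
electrode geometry, eye/muscle artifacts, inter-subject topography
variability, and broadband (non-carrier) microstate structure. Passing
tests therefore demonstrate the correctness and sensitivity of the
pipeline's machinery, not clinical performance on real EEG.

## Preprocessing

Only the deterministic steps of a clinical cleaning chain are
implemented: 0.1–40 Hz band-pass (4th-order Butterworth, applied
forward–backward as second-order sections so the filter is zero-phase and
does not shift microstate boundaries), a Q = 30 notch at 50 Hz, polyphase
resampling to 250 Hz, and bilateral-mastoid re-referencing that drops the
two mastoid channels (19 → 17). The filter family and order are package
choices; only the passband edges are externally specified. Manual steps
(ICA, visual bad-segment rejection, channel interpolation) are out of
scope. When a recording has no mastoid channels, re-referencing is a
logged pass-through, so already-reduced 17-channel data flow unchanged.

## Microstate stage

- **Clustering** is *polarity-invariant* modified K-means, not Euclidean
  K-means: microstate maps are sign-ambiguous under an oscillatory
  carrier, and plain K-means would split each class into a ± pair.
  Assignment maximizes squared spatial correlation; each template is
  re-estimated as the first principal component of its assigned maps,
  which provably does not decrease GEV within a restart. Defaults: 1000
  GFP-peak maps per subject, 50 restarts (20 in the heavier test
  configurations), tol 1e-6, max 300 iterations.
- **Template labeling.** Clusters are matched greedily by |correlation|
  to built-in canonical A–D reference maps (dipolar diagonal gradients
  for A/B, anterior–posterior for C, fronto-central radial for D, defined
  on tabulated 10-20 positions). For channel sets without tabulated
  positions the clusters keep their order and are labeled A–D with a
  notice. Labeling only fixes the feature ordering; it does not affect
  classification.
- **Backfitting** assigns every sample by maximal squared correlation
  with no temporal smoothing or minimum-duration rule. Zero-variance
  samples inherit the previous label.
- **Features** f1–f24: mean duration A–D (ms), occurrence A–D (1/s),
  coverage A–D, then the 12 ordered transition probabilities row-major
  (A→B, A→C, A→D, B→A, …, D→C). The coverage identity
  `coverage = occurrence × mean duration` holds exactly under these
  definitions. Alternative orderings of the 12 transition features exist
  in the literature and no single convention is universal; the ordering
  above is frozen and used everywhere, including Shapley reports.
- Templates are clustered once on peaks pooled from **all** subjects
  (the group-template convention). Microstate features are therefore
  computed before cross-validation; only standardization, selection and
  tuning are re-fit per fold. Template-level information shared across
  folds is a known, conventional approximation of this design.

## EMD stage

Classic sifting: strict local extrema, natural cubic-spline envelopes
with two extrema mirrored past each end (suppresses end swings), stop a
sift when the Cauchy criterion `Σm²/Σh² < 0.2` is met (standard default)
or after 100 iterations; stop extraction when the residual has fewer than
two extrema. The IMF count is standardized to the **first** nine modes —
early IMFs carry the oscillatory content; a shortfall is zero-padded with
a warning rather than an error so short synthetic recordings remain
runnable (60 s recordings typically produce 8–9 IMFs; 15-minute clinical
recordings produce 9–12). Skewness and kurtosis of zero-variance signals
are defined as 0. Among the 14 statistics, "Hjorth activity" equals the
population variance by definition; both slots are kept so the statistic
set and the 14-per-IMF arithmetic stay fixed. EMD runs on the full
continuous recording per channel; no epoching.

## Modeling

- LASSO uses the squared-loss objective with numerically encoded class
  labels (0/1, or 0/1/2 with one-vs-rest runs whose supports are
  unioned), implemented via scikit-learn's coordinate descent with the
  grid `λ ∈ [1e-4, 10]` (30 log-spaced values; sklearn `alpha = λ/2m`)
  and inner 3-fold CV. Columns are z-scored with training-fold statistics
  first — required for a uniform λ to be meaningful. If every weight
  shrinks to zero the single largest-|weight| feature at the smallest λ
  is kept, flagged.
- The logistic C is chosen by seeded log-uniform random search over
  `[1e-3, 1e3]` scored by inner 3-fold accuracy — a deterministic,
  model-free stand-in for sequential Bayesian tuning; with a
  one-dimensional, well-behaved search space the two approaches find
  equivalent optima.
- CV is label-stratified and subject-disjoint; 10 folds, repeated
  (default 10 repeats; 2 in the benchmark configurations), 95% CIs from
  the normal approximation over fold-level metrics. Binary positive
  class = the patient group. Three-class metrics: overall ACC, macro
  one-vs-rest AUC/SPE/SEN.

## Explanation

Exact linear Shapley values on the margin scale,
`φ_i = w_i (x_i − μ_i)` with the training-fold mean as background; for
CV, held-out-fold explanations are pooled with per-sample base values,
and unselected features get zero attribution (exact, since their
coefficient is zero). Local accuracy holds to machine precision.
Global importance is the mean |φ| per feature; modality shares are the
normalized sums over f1–f24 vs f25+.

## Known limitations

- Without temporal smoothing, backfit-derived mean durations are biased
  short whenever the instantaneous SNR dips (here, at every envelope
  trough): at SNR 4 label accuracy is ~92% but estimated durations are
  roughly a third of the generating means. Duration/transition recovery
  is therefore validated against the generated state sequence; absolute
  backfit durations should be interpreted comparatively, not as unbiased
  estimates.
- K = 4 is the only validated class count; other K values run but are
  untested.
- The EDF writer is minimal (16-bit, 1 s records, integer sampling
  rates) and intended for synthetic-cohort interchange, not for clinical
  archiving.
- CV repeats and tuning budgets in the shipped benchmark configurations
  are reduced (2 repeats, budget 10) relative to the package defaults;
  the defaults are recommended for real analyses.
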