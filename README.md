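# eegfuse

EEG-based classification of schizophrenia by **feature-level fusion of
microstate parameters and empirical-mode-decomposition (EMD) statistics**,
with LASSO feature selection inside subject-wise cross-validation,
logistic-regression classification, and exact Shapley-value attribution.

The package is aimed at computational-psychiatry researchers who want a
tested, fully reproducible implementation of this fusion pipeline that can
be exercised end to end on synthetic resting-state EEG with known ground
truth, and then applied to real recordings (EDF or delimited matrices).

## The method

For a preprocessed recording `x ∈ R^{N×T}` (N = 17 channels, 250 Hz):

**Microstate features (W, 24 values).** The global field power at sample
`n` is

    GFP_n = sqrt( Σ_i (x_in − x̄_n)² / N )

1000 GFP-peak topographies per subject are pooled across subjects and
clustered into K = 4 classes (A–D) by polarity-invariant modified K-means
(assignment by maximal squared spatial correlation, templates re-estimated
as first principal components, best of many restarts by global explained
variance). Every sample is backfit to its best template, and the label
sequence is summarized by mean duration, occurrence and coverage per class
(12 values) plus the 12 ordered transition probabilities — features
f1–f24.

**EMD features (E, N×9×14 values).** Each channel is sifted into
intrinsic mode functions (cubic-spline envelopes, Cauchy SD stopping
criterion), standardized to M = 9 IMFs, and each IMF is summarized by 14
conventional statistics (mean, max, min, quartiles, IQR, median, variance,
SD, kurtosis, skewness, RMS, Hjorth activity, peak-to-peak) — 2142 values
for 17 channels.

**Fusion.** The EMD tensor is averaged over the IMF axis without moving
channel/statistic positions and concatenated after the microstate block:

    R = [ W (24) | E_avg (N×C = 238) ]   →   262 features (f25 …)

**Modeling.** Per fold of repeated, label-stratified, subject-wise 10-fold
CV: z-scoring on the training subjects, LASSO selection
`min_ω Σ_i (y_i − ωᵀx_i)² + λ‖ω‖₁` with λ chosen by inner CV,
logistic regression with its inverse regularization tuned by seeded
random search, then AUC / ACC / SPE / SEN on the held-out subjects.

**Attribution.** Because the model is linear, Shapley values have the
exact closed form `φ_i = w_i (x_i − μ_i)` on the log-odds scale; the
package reports per-class global importances and the microstate-vs-EMD
contribution shares.

A synthetic-EEG generator provides the ground truth for all of this: a
semi-Markov microstate sequence (gamma segment lengths, row-stochastic
transition matrix), four fixed topographies under a 10 Hz rectified
envelope, 1/f + white noise at a controlled SNR, and a slow nonstationary
drift, with group contrasts planted in class-A duration, the B→D
transition probability and the drift amplitude.

## Worked example

```python
import numpy as np
from eegfuse.synthetic import default_group_specs, generate_cohort
from eegfuse.microstate import (gfp, find_gfp_peaks, sample_peak_maps,
                                cluster_microstates, assign_canonical_labels,
                                backfit, compute_parameters)

specs = default_group_specs(n_per_group=4, duration=30.0)
cohort = generate_cohort(specs, seed=42)
rec, truth = cohort[0]
print(f"subject {rec.subject_id}: {rec.n_channels} channels x "
      f"{rec.n_samples} samples @ {rec.sampling_rate:g} Hz")

pooled = np.vstack([
    sample_peak_maps(r, find_gfp_peaks(gfp(r)), 1000, seed=i)
    for i, (r, _) in enumerate(cohort)
])
ts = assign_canonical_labels(
    cluster_microstates(pooled, k=4, n_restarts=20, seed=0,
                        channel_names=rec.channel_names)
)
print(f"clustered {pooled.shape[0]} peak maps, GEV = {ts.gev:.3f}")
feats = compute_parameters(backfit(rec, ts), subject_id=rec.subject_id)
print("coverage A-D:", np.round(feats.coverage_fraction, 3))
print("occurrence A-D (/s):", np.round(feats.occurrence_per_s, 2))
```

prints

```
subject HC_000: 17 channels x 7500 samples @ 250 Hz
clustered 8000 peak maps, GEV = 0.692
coverage A-D: [0.251 0.254 0.236 0.259]
occurrence A-D (/s): [10.47 11.7  10.63 10.83]
```

i.e. the four classes each cover about a quarter of this control
subject's recording (the generator's transition matrix is uniform for
controls), and a GEV of 0.69 says the four templates explain most of the
topographic variance at this SNR.

The full pipeline is one call (or `eegfuse run-all` on the command line):

```python
from eegfuse.pipeline import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(
    output_dir="out", seed=7,
    synthetic=dict(n_per_group=16, duration=60.0),
))
print(report["modes"]["fused"]["AUC"])   # e.g. {'mean': 1.0, ...}
```

It writes per-mode feature matrices, fold-level metrics, confusion
matrices and Shapley importance tables under `out/`, plus a
`summary.json` comparing the microstate-only, EMD-only and fused models.

The CLI verbs `simulate`, `extract`, `fuse`, `classify`, `explain` and
`run-all` expose the same stages over persisted artifacts; see
`eegfuse --help`.

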