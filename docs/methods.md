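# Methods

This note documents the models, estimators and numerical choices behind
`netstab`, the assumptions they make, and what the synthetic benchmark
does and does not demonstrate.

## Signal model of the synthetic generator

Each simulated subject contributes a continuous multichannel recording
of band-limited oscillations plus broadband noise:

* **Oscillations.** Every channel carries a unit-amplitude cosine whose
  instantaneous frequency wanders inside the carrier band (default
  theta, 4–8 Hz): the frequency is redrawn uniformly from the band's
  interior every `freq_wander_s` seconds (default 0.25 s) and the phase
  is its cumulative integral. The wander makes *independent* channels
  decorrelate within a single 2-s epoch, so their phase-locking stays
  near the independence floor instead of the spuriously high values that
  fixed-frequency tones would produce.
* **Planted coupling.** For each pair in `coupled_pairs` (default
  F3→P3, F4→P4) the second channel's phase is the first channel's phase
  plus an offset δ(t) drawn i.i.d. from a von Mises(0, κ) distribution,
  with κ set per group (default κ_P = 1, κ_HC = 6, i.e. weakened
  long-range theta synchronisation in patients). Because the resultant
  length of a von Mises variable is I₁(κ)/I₀(κ), the sample-level PLV of
  a coupled pair has a closed form — the central analytic oracle of the
  test suite (κ = 2 → 0.6978).
* **Jitter holding.** δ(t) is held piecewise-constant over blocks of
  `jitter_hold_samples` samples (default 50 = 0.2 s at 250 Hz). A fresh
  draw every sample would constitute broadband phase noise that the
  theta band-pass filter averages away, erasing the planted contrast
  from filtered data; block-holding keeps each sample an exact von Mises
  draw while making the offset slow enough to survive filtering. The
  hold is short relative to the 2-s epoch, so per-epoch PLV estimates
  average ≈ 10 independent draws.
* **Background coupling.** Four homologous pairs (Fp1–Fp2, C3–C4,
  O1–O2, T7–T8) are coupled with a large, *group-invariant*
  concentration (κ = 20). Real scalp EEG always contains strong
  couplings from volume conduction and homologous synchrony; their
  presence also means the network-wide maximum edge weight is the same
  in both groups, so metrics normalised by the maximum (Onnela
  clustering) respond to the planted effect only through genuine
  topology, not through a shifting normaliser. Without them, the planted
  edge itself is the network maximum and clustering becomes an amplified
  proxy of it.
* **Noise.** Additive Gaussian white noise with `noise_sd` = 1 (SNR in
  the theta band ≈ 15 after filtering); an optional `1/f^α` exponent
  shapes the spectrum if desired (default α = 0, white).

Defaults mirror a small case/control study: 19 patients vs 24 controls,
500 two-second epochs per subject at 250 Hz on a 16-channel 10-20
montage with prefix-derived region tags. `generate_dataset` returns the
`truth` list — the feature-table columns in which the difference is
planted (`plv_theta_frontal-parietal`, `coh_theta_frontal-parietal`) —
empty when κ is equal across groups.

**What the generator does not emulate:** task-event structure, ocular or
muscle artifacts, realistic 1/f-dominated spectra, electrode drift,
inter-subject montage variability, or volume-conduction leakage beyond
the fixed background pairs. Passing the synthetic benchmarks therefore
demonstrates that the pipeline recovers a genuine band-limited coupling
difference under subject-wise validation — not that it would survive the
artifact load of real recordings.

## Preprocessing

Zero-phase filtering throughout (forward–backward application), because
any phase distortion would bias PLV directly: 4th-order Butterworth
band-pass (effective 8th order after the double pass) and an IIR notch
of quality factor 30 at 50 Hz. Band decomposition is applied to the
*continuous* recording before epoching, confining filter transients to
the recording edges. Epochs are non-overlapping, contiguous, with the
trailing remainder discarded. Independent-component artifact removal is
a pass-through hook (`ica_hook`): component-rejection criteria are
dataset-specific, and automating them here would be invention; the hook
accepts a user-supplied cleaning callable.

## Connectivity estimation

* **PLV**: analytic-signal (Hilbert) phases of the band-filtered epoch;
  10% of samples are discarded at each epoch edge before averaging the
  unit phasors (filter/Hilbert transients). All channel pairs are
  computed in one complex matrix product per epoch.
* **Coherence**: Welch cross-spectral densities with 1-s Hann segments
  and 50% overlap inside each 2-s epoch (3 segments), averaged over the
  in-band frequency bins. With 3 segments the null coherence has a
  substantial positive bias (~1/3); this bias is identical across
  groups and is characterised by a Monte-Carlo test rather than
  subtracted. The vectorised estimator is verified against
  `scipy.signal.coherence` on single pairs to 1e-10.
* Subject-level connectivity is the unweighted mean over that subject's
  epoch matrices (epochs are equal-duration).

## Network features

Connectivity matrices become weighted graphs (diagonal zeroed). Graphs
are kept complete by default — a proportional threshold would be an
extra free parameter; `threshold_p` enables it, retaining the strongest
`round(p·m)` edges with ties resolved by ascending edge index. Path
lengths use distance 1/w; global efficiency counts unreachable pairs as
zero; characteristic path length on a disconnected graph raises, with an
explicit largest-component fallback that warns. Weighted clustering is
the Onnela geometric-mean form normalised by the network maximum.
Node-level metrics are aggregated to network means to keep the feature
space compact; per-region connectivity is summarised as the mean over
all channel pairs spanning each unordered region pair (within-region
pairs for a region paired with itself). With 5 regions, 4 bands and
2 measures this yields (15 + 4) × 8 = 152 columns in a deterministic
order.

## Stability-driven selection

For each outer training set, subjects are split into `inner_folds`
(default 3) stratified grouped folds; a probe model is fitted on each
inner training part and its permutation importance evaluated on the
held-out inner subjects. The stability score of feature *f* is

    Stability_f = μ_f / (σ_f + ε),   ε = 1e-9,

with μ_f, σ_f the mean and sample (n−1) SD across folds; features are
ranked by score (ties: larger μ, then name) and the top k = 10 retained.
ε only guards σ = 0; at realistic importance scales it is numerically
invisible. The globally reported ranking aggregates one importance value
per outer fold (the mean of its inner estimates) and re-scores across
outer folds, so it reflects reproducibility across resampled training
sets; selection itself never sees test subjects.

Three estimator choices matter here and were genuinely open:

* **Probe model.** Permutation importance is always importance *of some
  fitted model*. With ~150 features and ~15 training subjects, flexible
  multivariate models (RBF-SVM, ridge logistic, random forest) spread
  credit across whichever members of a correlated feature cluster the
  particular fold happened to favour — their fold-wise rankings are
  dominated by credit-assignment noise, not by the features' own
  information. The default probe is therefore Gaussian naive Bayes: it
  treats features conditionally independently, so each feature's
  importance reflects its own discriminative content and is stable
  across folds. `CVConfig.importance_model` switches to `"logistic"`,
  `"random_forest"` or `"match"` (the configured classifier family).
* **Importance scoring.** The held-out score is the negative log-loss of
  the probe's probabilities — a strictly proper score that keeps
  discriminating between features when hard-label accuracy or AUC
  saturate at their ceiling, which happens quickly on 4–8-subject
  validation folds. Importance = baseline score − mean permuted score
  over `n_repeats` = 10 shuffles; all shuffles are evaluated in batched
  model calls.
* **Shapley attribution.** Computed for reporting/cross-checking on each
  outer fold's test subjects with the fitted final model: exact
  interventional Shapley values by full coalition enumeration for up to
  12 features (the value of a coalition marginalises excluded features
  over a background sample of training rows), permutation sampling
  beyond. Exactness gives local accuracy to machine precision
  (base + Σ attributions = prediction), verified against brute-force
  coalition enumeration in the tests.

## Modeling and evaluation

Outer loop: stratified 5-fold split of subjects (never of epochs).
Inner loop: the same grouped folds serve stability selection and the
hyperparameter grid search. Grids: C ∈ {0.1, 1, 10, 100},
γ ∈ {1e-3, …, 1} for the RBF-SVM; 100/300 trees × depth {None, 5, 10}
for the random forest. The grid is scored by held-out **log-loss** of
the calibrated probabilities, not accuracy: the final decision averages
probabilities across a subject's epochs, and on strongly separable folds
accuracy ties across most of the grid, which would silently select
degenerate calibrations. Standardisation lives inside the estimator
pipeline, so it is refitted on every training part. SVM probabilities
use Platt calibration (`probability=True`, fitted once on the full outer
training set after the search).

Subject-level predictions are the arithmetic mean of the subject's
epoch probabilities, thresholded at 0.5 (positive class = patients).
Metrics: accuracy, recall, specificity, and tie-corrected rank AUC;
"± SD" is across the five outer folds; 95% CIs for accuracy and AUC are
percentile bootstrap over subjects (default 10 000 resamples; resamples
missing a class are redrawn). Fold disjointness at the subject level and
exactly-once out-of-fold coverage are asserted at run time on every run.

`group_summary_test` computes Welch's t, Welch–Satterthwaite df, the
two-sided p and pooled-SD Cohen's d directly from group summary
statistics; recomputation from rounded summaries can differ in the last
digit from raw-data values (e.g. t = −2.04 vs a published −2.05), which
the package reports as computed rather than forcing agreement.

## Problem sizes used in the test suite

The planted-effect benchmarks run 12 + 12 subjects × 100 epochs × 16
channels with κ 1 vs 6 (20 seeds; AUC assessed on the first 10), and the
label-permutation null uses the same cohort at 30 epochs per subject
(20 seeds). These sizes give per-feature effect sizes and fold counts at
which the expected behaviour (detection, top-3 stability rank of the
planted feature, chance-level null) is statistically unambiguous while
keeping a full 40-run suite in a few minutes of CPU time. Bootstrap
iterations are reduced (500–1000) in tests that do not assert CI
properties.

## Known limitations

* Coherence inherits the 3-segment Welch bias floor; comparisons across
  configurations with different epoch lengths are not bias-matched.
* Gaussian naive Bayes importance ignores feature interactions by
  design; a discriminative pattern expressible only jointly (and not
  marginally) would be under-ranked. The final classifiers, fitted on
  the selected set, can still exploit interactions among the survivors.
* The stability score μ/(σ+ε) is scale-dependent across importance
  estimators; scores from different probes are not comparable.
* Characteristic path length's largest-component fallback changes the
  metric's support; it is flagged with a warning whenever used.
* With a single channel in a region, the region's within-region pair
  feature is undefined and the column is omitted (deterministically).
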