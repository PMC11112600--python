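# Methods

This note documents the models, the numerical choices behind them, and what
the synthetic benchmark does and does not establish.

## Problem setting

Clinical muscle strength is graded on a 5-level scale (1 = flicker of
contraction, 5 = normal) by manual muscle testing.  The package implements a
computational stack that grades strength from wearable recordings — four
synchronized channels (two surface-EMG and two piezoelectric strain traces)
sampled at 1 kHz — and then refines each clinical grade into five
unsupervised sub-levels, reported as fractional grades g.0, g.2, …, g.8.

## Preprocessing

Each channel is band-pass filtered to 10–450 Hz with a 4th-order Butterworth
filter applied forward–backward (zero-phase), so the relative timing of the
electrical and mechanical channels is preserved.  The filtered signal is cut
into sliding windows of 200 samples with a step of 100 (yielding
`floor((L-200)/100)+1` segments per recording), and each subject's channels
are min–max normalized to [0, 1] using that subject's full-signal extrema:

    s_i = (r_i − min R) / (max R − min R)

The training extrema are stored with the model checkpoint; at inference time
unseen data are mapped with the stored bounds and clipped to [0, 1].  A
constant channel is an error during training (broken fixture) and maps to
zeros with a warning at inference (detached sensor).  Whether the extrema are
taken before or after filtering is not externally constrained; they are taken
over the *filtered* signal, matching the pipeline order.

Signal-to-noise ratio is reported as `20·log10(V_s/V_n)` where V_s and V_n
are RMS ("effective") amplitudes over the active and rest samples.

## The 5-class classifier

Architecture, per 4×200 input segment:

1. **Dilated temporal convolutions.**  Three convolution layers, each with 40
   filters of size 5 and dilation 1, 2 and 3 respectively, arranged as
   parallel branches over the input, batch-normalized per branch and summed,
   then ReLU.  Convolutions are bias-free ("same" padding); the batch norms
   supply the offsets.
2. **Average pooling** of size 40 (kernel = stride), smoothing each filter
   map to 5 values — an envelope-energy profile per filter.
3. **Attention stage.**  The 40 pooled filter maps are treated as tokens of
   width 5.  Six attention heads compute `softmax(Q Kᵀ / k) V` with k = 200
   (the raw segment length — the model's literal scaling rule, switchable to
   √d_k via config), with per-head bias-free maps Q, K: 5→4 and V: 5→3.  The
   concatenated heads are mixed back to width 5 by W^O and added to the input
   (residual), and a bias-free position-wise feed-forward pair 5→228→14 maps
   each token to 14 features.  Flattening the 40 tokens gives the 560-dim
   feature.  A parameter-free batch standardization conditions this feature
   before the head.
4. **Classification head.**  560→256→64→K dense layers (ReLU, dropout 0.5
   after the two hidden layers) and softmax.  K = 5 for clinical grades,
   K = 25 after refinement.

### Calibration of the unstated widths

The published constants are: 40 size-5 filters per conv layer, dilations
1-2-3, pooling size 40, 6 heads, a 560-dim flattened feature, a 256/64 head,
and 167,781 trainable parameters in total.  These jointly pin the remaining
widths.  A *serial* 40→40→40 stack is arithmetically impossible (its convs
alone cost 17,160 parameters while head + feature constraints leave only
7,392 for everything before the head), which forces the parallel-branch
reading of "three layers with expansion factors 1, 2, 3".  Within the 7,392
budget the attention solution above (d_k = 4, d_v = 3, residual, FFN hidden
228, output width 14) is exact:

    conv 3·(4·5·40) = 2400, batch norms 3·80 = 240,
    QKV 6·(5·4·2 + 5·3) = 330, W^O 18·5 = 90, FFN 5·228 + 228·14 = 4332
    → front end 7392;  head 160,389;  total 167,781.

The serial stack remains available (`tcn_layout="serial"`) but is not
calibrated.  Receptive fields: 1 + (k−1)·max(d) = 13 for the parallel
layout, 1 + Σ(k−1)·d = 25 for the serial one.

### Numerical choices

* **Score scaling vs. trainability.**  Dividing attention scores by 200
  (rather than √d_k = 2) would flatten the softmax to uniform at standard
  initialisation scales, collapsing every token onto the token mean and
  silencing the Q/K gradients.  The Q/K matrices are therefore initialised
  with spread `√scale / (d_k^{1/4} √d_in)` so the scaled scores have O(1)
  dispersion from the start.  This preserves the published formula exactly
  while keeping it optimizable.
* **Output layer** is initialised near zero, so training starts from the
  uniform prediction (first-epoch loss ≈ ln K).
* Training: categorical cross-entropy, Adam at learning rate 1e-4, batch 72,
  dropout 0.5, 500 epochs by default; the parameters with the best validation
  accuracy are kept.  All randomness (init, shuffling, dropout) derives from
  one config seed.
* Per-recording grades aggregate per-segment predictions by majority vote,
  ties resolved toward the higher grade.
* Cross-validation: 10 resampled 80/20 splits, stratified by grade and
  grouped by subject (no subject on both sides); falls back to segment-level
  stratification, with a warning, when a grade has fewer than two subjects.

## Deep-clustering refinement (25 sub-levels)

1. **Autoencoder.**  Encoder = the trained classifier's feature extractor
   (through the 560-dim feature, head removed) plus a linear latent map
   560→160; decoder = 160→209→800 dense layers (ReLU between) reconstructing
   the flattened 4×200 segment.  Trained under
   `L_rec = (1/N) Σ ‖x_i − x̂_i‖²` (squared Euclidean norm on the flattened
   800-vector, averaged over samples only).  When the encoder is transferred
   from the trained classifier it is kept *frozen* (weights and
   normalisation statistics — batches are encoded in eval mode): it already
   carries the learned representation, and letting the reconstruction
   objective rewrite it measurably erodes the discriminative geometry the
   clustering depends on.  The latent map is set to a random orthonormal
   projection — an isometry, so latent geometry mirrors feature geometry —
   and the warm-up fits the decoder to this fixed code.
2. **Per-grade clustering.**  For each clinical grade independently:
   * each segment's code is averaged with its temporally adjacent
     overlapping windows from the same recording (window of 3) — the
     sub-level is a slowly varying property of the contraction, and
     smoothing suppresses per-window estimator noise;
   * the clustering kernel operates in a frozen *whitened* frame: the top
     10 principal components of the grade's codes (10 is the canonical
     working dimensionality of deep embedded clustering), because an
     isotropic kernel on the raw 160-d codes is dominated by
     reconstruction-salient nuisance directions;
   * K = 5 centres are initialised by K-means in that frame (20 restarts,
     best inertia kept; centres are lifted back into the full latent space,
     where they remain ordinary parameters), and decoder and centres then
     descend `L = L_rec + λ·KL(P‖Q)` with λ = 0.1.  Q is the student-t soft
     assignment (α = 1) and P the sharpened target distribution, refreshed
     every 5 epochs; training stops when fewer than 0.1 % of hard
     assignments change between refreshes, and a degeneration guard rolls
     back to the last healthy refresh if the self-sharpening starves a
     sub-cluster below a quarter of its parity share.  Centres take plain
     gradient steps (not Adam): the clustering gradient is weak, and
     scale-free adaptive steps would amplify its batch noise into drift.
   A numerical floor of 1e-10 inside the KL guards against underflow.
   Analytic KL gradients (verified against finite differences in the tests)
   flow into both the latent codes and the centres.
3. **Fractional labels.**  Within each grade the five sub-clusters are
   ranked by the mean RMS amplitude of their member segments measured on the
   *filtered, un-normalized* signal — the most direct physical surrogate of
   contraction intensity — and assigned sub-indices 0..4, i.e. fractional
   grades g.0 … g.8.  This ordering rule is an interpretive choice: any
   monotone strength surrogate would do.
4. **25-class fine-tuning.**  The feature extractor is frozen (features are
   computed once in eval mode, so the frozen front end is bit-identical
   afterwards) and a fresh 256/64/25 head is trained on the refined labels
   (Adam 1e-3, 200 epochs, stratified 80/20 *segment-level* hold-out — with
   one subject per sub-level cell a subject-wise split would leave whole
   cells unseen by construction).

With the calibrated defaults the refinement model counts exactly 299,601
trainable parameters: front end 7,392 + latent map 89,760 + decoder 201,649
+ 5 cluster centres of width 160 (800).  Per-grade clustering is the default
(5 clusters × 5 grades); a flat 25-way alternative is a config switch away.

## Clustering validity indices

Davies–Bouldin, Calinski–Harabasz and silhouette are computed directly from
their definitions with Euclidean distances; the tests cross-check all three
against scikit-learn on random instances to 1e-8 or better.  Note the
silhouette definition `(b−a)/max(a,b)` genuinely ranges over [−1, 1]; no
clamping to [0, 1] is applied.  Singleton clusters contribute 0.

## The synthetic benchmark

No public recording set exists for this device class, so the package ships a
generator whose output has the statistical structure the models assume.

* **sEMG** is amplitude-modulated band-limited Gaussian noise (the standard
  phenomenological surrogate for the interference pattern): the envelope
  rises over t0, holds for t1, falls over t2 (half-cosine ramps), times a
  carrier filtered to the grade's spectral band, plus a white noise floor of
  0.01 (arbitrary volts).
* **Strain channels** respond to strain rate: a positive Gaussian pulse
  spanning the rise and a negative one spanning the release (t2 = t0, so the
  peak-to-peak spacing is exactly t0 + t1), plus a noise floor 5× smaller
  than the sEMG floor (charge-amplified piezo electronics are quiet compared
  to skin-electrode noise).
* **Grade cues are categorical**, mirroring the qualitative differences
  between clinical grades: each grade owns a disjoint spectral band
  (centres 80·1.38^(g−1) Hz ≈ 80–290 Hz — physiological median-frequency
  territory whose oscillation periods sit inside the convolution stage's
  13-sample receptive field — width factor 1.15), a characteristic rise
  time (0.45 s down to 0.23 s), and a strain amplitude that steps
  categorically (0.008/0.04/0.14/0.4/1.0): clinically, grade 1 produces a
  flicker without joint movement, grade 2 moves only with gravity
  eliminated, grades 3–5 complete the range with rising force.  sEMG base
  amplitudes grow 2.5× per grade, putting the strongest grades near the
  device-class ~40 dB SNR and grade 1 near the detection floor.
* **Sub-levels are within-grade intensity gradations**: amplitude
  multipliers 0.6/0.8/1.0/1.2/1.4 (so sEMG amplitude is strictly increasing
  in (grade, sub-level) even across boundaries), a force-steadiness ladder
  (9 Hz tremor ripple of the envelope, depth 0.5·0.7^j, also wobbling the
  strain trace during the hold — the step keeps adjacent sub-levels several
  estimator standard deviations apart per 200-sample window), and slightly
  faster rise (×0.97 per sub-level).  A pure per-subject amplitude
  multiplier would be *invisible* after per-subject min–max normalization
  at realistic SNR, which is why the steadiness and timing correlates of
  contraction intensity are planted alongside it.
* **Benchmark sizing.**  5 subjects per grade, one per sub-level cell, each
  contributing one 4.2 s recording whose sustained-hold phase (2.5 s)
  yields exactly 24 windows: 600 activity segments, 24 per cell, matching
  the scale of the reference training corpus (~597 segments).  Windows are
  taken from the hold phase — the stationary "activity segments" — because
  the rise/fall transients are non-stationary nuisance for both classifier
  and clustering.  Subject-level jitter: 2 % on amplitude, 1 % on band
  centre.  The manifest regenerates a dataset bit-exactly.

**What passing tests show — and don't.**  Recovery of the planted grades and
sub-levels demonstrates that the pipeline's machinery (filtering, windowing,
normalization, classifier, deep clustering, ordering rule) is implemented
correctly and can extract precisely the kinds of structure it presumes.  It
does not validate clinical performance: real sEMG has motor-unit structure,
non-stationary spectra, electrode artifacts and inter-session variability
the generator does not attempt (no motor-unit recruitment model, no
patient-specific spectra).

## Problem sizes used

Desk-scale runs train the 5-class model for 100 epochs (the published recipe
uses 500) on the 600-segment benchmark with a subject-wise 4:1 split;
decoder warm-up uses 30 epochs (transferred encoder frozen) and per-grade
joint clustering at most 80 epochs with convergence-based early stopping.
These sizes are the package's test defaults and run in minutes on a single
CPU core.

## Known limitations

* The calibration (parallel conv branches, attention widths, FFN widths,
  latent width 160, decoder hidden 209) reproduces the printed parameter
  counts exactly, but other unpublished solutions exist; the chosen one is
  documented above and pinned by tests.
* The per-grade clustering trains one autoencoder copy per grade after the
  shared warm-up; with a transferred encoder the feature extractor stays
  fixed throughout, so the joint phase moves the decoder and the cluster
  centres.  On this benchmark the self-training refinement converges within
  a few target refreshes and contributes little beyond its K-means
  initialisation — the loss trajectories in the cluster state record this.
* The fractional-grade ordering depends on the RMS-amplitude surrogate;
  sub-levels of a grade whose amplitudes overlap heavily may be ordered
  differently than a clinician would order them.
* The generator's grade/sub-level parameter ladders are phenomenological
  choices, not fitted to patient data.
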