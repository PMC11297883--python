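# Methods

## The pipeline

An EEG recording is a channels × samples matrix in microvolts with an
ordered montage. The analysis unit is the *epoch*: a non-overlapping
fixed-length window (default 21.25 s) starting at sample 0, with the
trailing remainder discarded so every downstream matrix has a fixed size.
No filtering, re-referencing, artifact rejection or resampling is applied
before the transform; the wavelet stage is the only spectral processing.

Each channel is decomposed with the continuous wavelet transform (CWT)
using the real Gaussian-derivative mother wavelet of order 6 ('gaus6') and
the integer scale grid a = 1…30, with the conventional a^(-1/2)
normalisation. The transform is evaluated by PyWavelets with same-length
output; edge coefficients are zero-padded and deliberately kept, since the
correlation stage consumes every column. The per-channel scalograms
(n_scales × L) are stacked channel-major — all scales of channel 0, then
channel 1, … — and the sample Pearson correlation between every pair of
the C·n stacked rows forms the (C·n)² correlation image. Correlations use
signed coefficients, not magnitudes. A zero-variance row (e.g. from an
all-zero channel) correlates 0 with everything and 1 with itself. Because
Pearson correlation is scale-invariant, the population/sample covariance
distinction cancels.

The image has a block structure that all attribution logic relies on:
entry (r, s) relates channel ⌊r/n⌋ at scale r mod n to channel ⌊s/n⌋ at
scale s mod n, so the n × n block (i, j) summarises the cross-scale
coupling of channels i and j, and the diagonal blocks hold each channel's
own scale–scale structure (its spectral shape).

## The classifier

The default architecture is five conv/pool blocks (8, 16, 32, 64, 128
same-padded 3×3 ReLU filters, 2×2 stride-2 max pooling with floor
division: 360 → 180 → 90 → 45 → 22 → 11), global max pooling to 128,
dropout 0.2, Dense(32, ReLU), batch normalisation, and a softmax over the
three classes. Same padding and floor-division pooling are forced by the
layer-size arithmetic (a 3×3 conv that preserves 360, and 45 → 22
pooling). Training: Adam with learning rate 10⁻⁴ (β₁ = 0.9, β₂ = 0.999,
ε = 10⁻⁷), sparse categorical cross-entropy with per-sample weights
w_c = N/(K·N_c) (so Σ N_c w_c = N: total loss mass is preserved, only
shifted toward minority classes), 700 epochs, batch size 15.

Evaluation uses stratified k-fold cross-validation (k = 10). Per
iteration, one of the k−1 training folds — chosen by a seeded stratified
split — is held out as a validation set; the epoch with the highest
validation accuracy (ties broken by lower validation loss) defines the
checkpoint, and the checkpointed weights evaluate the test fold.
Fold granularity is configurable: `grouping="epoch"` stratifies epochs
directly (epochs of one subject can then appear on both sides of a split),
`grouping="subject"` keeps each subject's epochs in a single fold. Both
are provided because either protocol is defensible for epoch-level
classification; subject grouping is the stricter, leakage-free reading.
Per-fold metrics are accuracy plus macro one-vs-rest sensitivity,
specificity and precision (unweighted mean over classes; a class with a
zero denominator is dropped from that metric's mean with a warning), and
folds aggregate as mean ± sample (n−1) SD.

The network runs on the package's own NumPy engine (`eegcorrcam.nn`):
im2col + BLAS convolutions, analytic backward passes for every layer,
and Adam. The backward pass is verified against central finite
differences in the test suite (absolute agreement ~10⁻⁹ in float64), and
the same machinery supplies the feature-map gradients for Grad-CAM, so
saliency and training share one gradient implementation. Tensors are
float32; argmax ties in pooling resolve to the first (row-major)
occurrence, and class-prediction ties resolve to the lowest class index.

## Grad-CAM and channel-pair attribution

For a target class, the feature maps A_k of the final convolutional layer
are weighted by α_k, the spatial mean of ∂(class score)/∂A_k; the map
ReLU(Σ_k α_k A_k) is upsampled bilinearly to the input size and min–max
normalised to [0, 1] (an all-zero rectified map is returned as zeros with
a warning). Two class scores are available. The default differentiates
the *softmax probability* (seed p_c(e_c − p)), which is contrastive:
evidence shared between classes cancels, and classes that the network
encodes partly as "not the others" still produce localised maps. The
pre-softmax logit is available as `target="logit"` and is used by the
analytic oracle tests, where the class score is constructed by hand.

A heatmap is aggregated into channel-pair scores over the block grid:
score(i, j) = mean of the heatmap over block (i, j), averaged with block
(j, i). Max-over-block is available as an alternative reducer. All
C(C+1)/2 unordered pairs are scored, *including self-pairs*: a channel
whose spectrum differs between classes lights up its own diagonal block,
and hiding that would misrepresent the saliency. The `cross_ranking`
view restricts to distinct-channel pairs — the reading used when the
question is "which inter-channel correlation mattered". A subject-level
consensus ranks pairs by their mean rank across the subject's epochs
(lower is better, ties by channel order), rewarding saliency that is
consistent across segments rather than strong in one.

## The synthetic generator

Each class is defined by a channel pair that shares a latent oscillation.
Every channel is unit-variance noise — pink (1/f amplitude) by default,
matching the qualitative EEG spectrum — and the two planted channels are
√(1−ρ²)·noise + ρ·latent with a latent shared between them, so their
expected Pearson correlation is ρ². The latent is band-limited filtered
white noise (default 8–12 Hz, the alpha band) rather than a pure tone, so
scalograms show realistic spectral spread and the task is not degenerately
easy. Coupling is injected in the time domain, before the CWT, so planted
structure must survive the full transform for the pipeline to find it.
Defaults mirror the clinical geometry the package targets: 12 channels,
500 Hz, 180 s, three classes (coupled pairs Fp2–P4, F3–T4, Fp1–F8 — one
frontal–parietal, one frontal–temporal, one frontal–frontal pair, all
distinct). One global seed; each recording draws from a substream derived
from (seed, subject index), so any recording is reproducible in isolation.

What the generator does *not* emulate: volume conduction (all non-planted
channels are independent, whereas real EEG channels are broadly
correlated), artifacts, nonstationarity, and any physiologically
meaningful ADHD/CD signature. Passing tests therefore demonstrate that
the pipeline recovers *detectable planted structure* end to end — not
that it measures anything clinically valid.

## The scaled-down study

The simulation study exercised by the test suite uses 3 classes × 20
recordings of 12 channels at 250 Hz for 64 s (3 epochs each, 180 epochs
total), coupling ρ = 0.85, a 20-scale CWT (240 × 240 images), and
training budgets of at most 50 epochs. Two reduced architectures are
used, chosen in pilot runs:

* **Accuracy leg** — a thin five-stage stack (4, 8, 16, 32, 64 filters),
  6 epochs, lr 10⁻³: validation accuracy saturates within two to three
  epochs, and 10-fold cross-validation scores well above the 85% bar.
* **Attribution leg** — an ensemble of three two-stage stacks (16, 32
  filters; 30 epochs; seeds 0–2). Two design facts drive this. First,
  resolution: with only two pooling stages the final conv layer stays at
  120 × 120, so each CAM cell covers 2 px against 20 px channel blocks;
  deeper stacks localise correctly but coarsely — at a 15 × 15 final conv
  each cell spans 16 px and the upsampled blob bleeds into neighbouring
  blocks, diluting block-mean scores. Second, feature idiosyncrasy: a
  single small network sometimes encodes one class largely through
  features of *other* classes' blocks, and its CAM for that class then
  mislocalises even when classification is perfect. The ensemble
  addresses this twice over: subject-level predictions average the
  softmax outputs of members whose checkpoint validation accuracy
  reaches 0.9 (ordinary validation-based model selection, using no test
  data; the single best member is the fallback), and attribution uses a
  *median*-rank consensus over every (member, epoch) attribution, which
  tolerates one mislocalising member in three. Attribution quality,
  unlike accuracy, is resolution- and feature-stability-limited.

On held-out subjects (7 per class, classified by majority vote over their
epochs), the planted pair is expected among the top-3 cross-channel
consensus pairs for at least 80% of correctly classified subjects, and
top-1 recovery is tested against the 1/66 cross-pair chance rate
(binomial, α = 0.01, ≥ 20× chance). The planted channels' *self*-pairs
legitimately rank high as well — the latent changes those channels' own
spectra — which is why recovery is scored on the cross-pair ranking.

## Numerical conventions and edge cases

* Epoch length = ⌊epoch_seconds · fs⌋ samples (exact for 21.25 s × 500 Hz
  = 10,625); recordings shorter than one epoch yield no epochs, not an
  error.
* CSV input carries no metadata, so the sampling rate must come from
  configuration; EDF supplies its own. Channels are always reordered to
  the configured montage, and a missing montage channel is an error
  naming the channel.
* The minimal EDF writer quantises each channel to 16 bits over its
  physical range (round-trip error ≤ range/2¹⁵); it exists for round-trip
  testing and small exports.
* Heatmap upsampling is bilinear by default (nearest available); min–max
  normalisation is per heatmap, so maps are comparable in shape, not in
  absolute magnitude, across epochs.
* Cross-validation seeds: fold assignment, validation split, weight
  initialisation, shuffling and dropout all derive from the single run
  seed (fold f uses seed·10⁴ + f), making full runs bit-reproducible on
  one platform.

## Known limitations

* The NumPy engine targets exactly the layer family this architecture
  needs (stride-1 odd-kernel same convolutions, 2×2 pooling); it is not a
  general framework, and large inputs train slowly compared to GPU
  frameworks.
* Grad-CAM's localisation is bounded by the final conv resolution; for
  the full 360 × 360 network (11 × 11 final conv) each CAM cell spans
  roughly one channel block, so block-level rankings are meaningful but
  sub-block detail is not.
* Batch normalisation statistics come from training batches (momentum
  0.99); very short trainings can leave running statistics noisy — the
  checkpoint criterion operates on validation metrics computed in
  inference mode, which mitigates but does not remove this.
* With epoch-level folds, epochs of one subject can occur in both train
  and test sets; subject-level conclusions should use
  `grouping="subject"`.
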