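# Methods

This note documents the models implemented in `neuroflow`, the assumptions
behind them, the numerical conventions, and what the synthetic-data
experiments do and do not demonstrate.

## Problem setting

Three-class screening (AD / MCI / HC) from speech feature vectors, trained
with the help of an *unpaired* EEG cohort that contains only AD and HC
subjects. The working hypothesis is the clinical disease continuum: cognition
degrades progressively HC → MCI → AD, so class representations should lie on
a smooth trajectory in a well-chosen latent space, and the missing MCI
region of the EEG modality can be bridged by interpolation between the AD
and HC anchors.

## EEG biomarkers

* **Time domain** — mean, peak, variance, standard deviation, skewness,
  kurtosis, RMS per channel, stacked feature-major. Conventions: peak is the
  maximum absolute amplitude; variance/std are population (ddof 0); skewness
  is sample skewness and kurtosis excess kurtosis, both defined as 0 for a
  constant channel (the moments are otherwise undefined there).
* **Frequency domain** — Welch PSD with 2 s Hann windows and 50 % overlap
  (the estimator is a package choice; any consistent estimator yields the
  same relative quantities). Band power is rectangular bin integration over
  [f_lo, f_hi) for δ [0.5,4), θ [4,8), α [8,13), β [13,30), γ [30,100) Hz,
  with the γ upper edge capped at Nyquist; clinical resting-state data is
  typically low-pass filtered near 45 Hz, so γ is effectively 30–45 Hz
  there. Relative powers are normalized by the five-band sum; the three
  ratios (θ/α, δ/α, (δ+θ)/(α+β)) use the same absolute powers; the median
  frequency is the smallest frequency at which the cumulative PSD over the
  analyzed range (0.5 Hz to the capped edge) reaches half its total; the
  spectral entropy is the Shannon entropy of the normalized PSD divided by
  log K (base-invariant, 1 = flat spectrum). Zero denominators are epsilon-
  guarded with a warning.
* **Wavelet** — db4, 5 levels, sub-bands A5, D5…D1; per sub-band the energy,
  coefficient SD, and Shannon entropy of the squared-coefficient
  distribution (0·log 0 := 0). Periodization boundary mode is used so the
  sub-band energies sum exactly to the signal energy — this conservation is
  asserted in the tests.
* **Multiscale entropy** — sample entropy −ln(A/B) with embedding m = 2,
  strict Chebyshev matching (< r), self-matches excluded, and the same
  template count N−m at both lengths; tolerance r = 0.15 × SD of the
  original channel, held fixed across scales so entropy changes across
  scales reflect structure, not tolerance drift. Coarse-graining averages
  non-overlapping windows (length ⌊N/τ⌋ output); no additional decimation
  is applied before coarse-graining. Scales 1–20. Degenerate scales (no
  template matches) either raise or are filled with NaN, per configuration.
* **Connectivity** — PLI per channel pair: band-pass FIR (order ≈ 3·fs/f_lo,
  zero-phase filtering) in the α band, Hilbert phases, one filter length of
  edge samples discarded, then |⟨sign sin Δφ⟩|. PLI is invariant to
  per-channel amplitude scaling and blind to zero-lag coupling by
  construction. ROI connectivity averages PLI over all electrode pairs
  between two regions, for the 10 unordered pairs of the standard 10–20
  five-region grouping (Frontal / Central / Temporal / Parietal /
  Occipital).

## Dimensionality reduction

PCA retains the smallest k whose cumulative explained variance reaches the
threshold (default 0.95). The masked autoencoder masks a Bernoulli(0.3)
subset of *entries* per row (entry-level masking is the natural granularity
for flat feature vectors), zero-fills them at the encoder input, and scores
the reconstruction only at masked positions; the decoder reconstructs the
full vector but unmasked outputs cannot influence the loss. Training: Adam
with weight decay 1e-4, batch 64, up to 100 epochs, early stopping on a held
10 % validation split with patience 5. The validation mask is drawn once per
run so the early-stopping signal is not resampled noise. Early stopping
restores the best parameters *and* the batch-norm running statistics
recorded with them.

## Cross-modal alignment

Two encoders (input → hidden → 128, batch-norm + ReLU + dropout 0.2
between; speech hidden 256, EEG hidden 64 for narrow inputs or 512 for wide
ones) feed a shared linear 3-class head, a binary modality discriminator
(128→64→1) behind a gradient-reversal layer, and three class centers.

* Classification: cross-entropy weighted by reciprocal class proportions of
  the speech training fold, normalized by the batch weight sum.
* Center loss: mean Euclidean (first-power) distance to the class center.
  Centers are updated by a dedicated SGD optimizer (lr 0.5) on the
  closed-form gradient of the unweighted center loss over detached latents,
  not by the main Adam step — this keeps the center dynamics from being
  distorted by the loss weighting.
* Consistency: MSE between same-class mean latents of the two modalities,
  averaged over classes present in both batches; MCI never contributes
  (there is no EEG MCI data to be consistent with).
* Domain adversary: BCE on the discriminator, with the gradient-reversal
  factor ramping linearly from 0 to 0.1 across epochs (a sigmoidal DANN-
  style ramp is available via config). Early training thus prioritizes
  discriminative features; modality invariance is enforced progressively.
* Total: `L_cls + 0.05·L_center + 0.1·L_domain + 5.0·L_consist`; the
  identity is logged per epoch and asserted in tests.

Pseudo-MCI anchors are sampled per batch as convex combinations
α·z_AD + (1−α)·z_HC of same-batch AD/HC latents (both modalities pooled),
α ~ Beta(2,2) — symmetric and interior-concentrated; the distribution's
parameters were an open choice. The anchors act as spatial regularization:
they enter the classification loss with the MCI label at half weight and
the center loss toward the MCI center; both uses are togglable because the
exact losses applied to the anchors are a genuinely open design point.

Data loading is asymmetric: speech is the primary modality covered exactly
once per epoch (shuffled batches of 64); EEG cycles through an independent
iterator that reshuffles whenever exhausted. Optimization: Adam, lr 1e-3
halved every 30 epochs, L2 decay 1e-3, 200 epochs.

## Conditional rectified flow

The velocity network embeds the state (linear), the scalar time t (two
fully connected layers with SiLU; t is fed as a plain scalar, no sinusoidal
embedding), and the 128-dim condition (same shape), sums the three
embeddings at width 256, applies 3 residual blocks (two FC + SiLU, layer
normalization) and projects back to the state dimension. Training draws
t ~ U[0,1] and x0 ~ N(0,I) per batch and minimizes the mean (over batch and
dimensions) of ‖v − (x1 − x0)‖²; dividing by the dimension is the package's
reduction convention (multiply by dim to recover per-sample squared norms).
The training pair couples each EEG latent x1 with a random same-class
speech latent as condition c, re-drawn every epoch — the pairing rule is
not dictated by the unpaired-data setting and random same-class matching is
the least-assumption choice. Sampling is N = 10 explicit Euler steps; the
straight-path construction makes few steps sufficient, and a constant field
is integrated exactly for any N (asserted).

State and condition default to the 128-dim aligned subspace, keeping the
generated latents directly fusable; the state dimension is configurable.

In the pipeline the latent representation handed to the fusion head is the
average of `n_gen_samples = 5` Euler samples with independent x0 draws — a
Monte-Carlo estimate of the conditional mean over the noise prior. A single
draw carries sampling variance that measurably destabilizes downstream
accuracy on small validation sets; the conditional-mean estimate removes it
at negligible cost. Set `n_gen_samples=1` for single-draw behavior.

## Fusion and evaluation

Branches (input → 128, BN + ReLU + dropout 0.3) are concatenated to 256 and
re-weighted by a squeeze-and-excitation gate. Because the features are flat
vectors, the "squeeze" over a singleton spatial axis is the identity, so the
gate is computed directly from the 256 channels through the 256→32→256
bottleneck and a sigmoid. The head is a 64-unit MLP. Training: Adam (decay
1e-4), batch 16, early stopping patience 20 on an internal validation split,
plateau-based lr halving (factor 0.5, patience 10) as the adaptive-lr
strategy.

Metrics are one-vs-rest from the 3×3 confusion matrix (rows true, columns
predicted, order AD/HC/MCI; fractional fold-averaged matrices are
supported): sensitivity, specificity, precision, F1; accuracy =
trace/total; macro averages are unweighted class means; macro AUC is
one-vs-rest on predicted probabilities. Metrics of a class absent from the
truth are undefined and excluded from macros with a warning.

The cross-validation protocol stratifies the speech table into 5 folds; the
EEG table is split 4:1 once per seed and reused unchanged across folds; a
runtime guard asserts empty train/validation subject intersections. Models
are independently initialized per fold, and results aggregate as mean ± SD
over folds, then over seeds. Six ablation modes are runnable: `align`,
`align+noise`, `flow-only`, `latent-only`, `align+flow-concat`,
`align+flow+attention`.

## Synthetic data

`generate_continuum_cohort` draws class anchors in an 8-dim latent space
(HC anchor Gaussian; AD anchor offset so the continuum has a definite
direction; MCI at fraction `mci_position` — default 0.5, a free parameter,
since no quantitative MCI position is established), maps them through
random affine maps to 128-dim speech and 32-dim EEG feature spaces, and
adds isotropic Gaussian feature noise. Latent positions are exactly the
class anchors; all within-class variability is feature noise — the simplest
model under which alignment and flow recovery have known targets. Per-
subject random streams are counter-derived from the cohort seed, so
enlarging a cohort never changes earlier subjects. EEG rows exist only for
AD and HC.

`generate_band_structured_eeg` sums one sinusoidal carrier per band
(2 / 6 / 10 / 15 / 35 Hz for δ/θ/α/β/γ — each carrier inside its analysis
band so band attribution is unambiguous) with per-channel random phases and
white noise. The AD-like profile elevates δ/θ and suppresses α (amplitudes
2.0/1.5/0.5/0.4/0.2 µV vs 0.8/0.8/2.0/0.6/0.3 for HC-like), emulating the
spectral slowing contrast; the amplitudes are package choices at a
realistic contrast, not measured values.

What passing on this data shows: the pipeline's optimization, losses,
geometry handling and protocol behave as designed when the continuum
assumption holds exactly and noise is Gaussian. What it does not show:
performance on real cohorts, where features are non-Gaussian, classes are
not affine images of a 1-D continuum, modality maps are nonlinear, and
label noise exists. No claim about real-data accuracy is made or implied.

## Problem sizes and numerical choices

The default configurations carry the reference training lengths (alignment
200 epochs, flow 500, MAE/fusion early-stopped). The test suite and the
acceptance script run scaled-down problems chosen as the package's own
study sizes: parameter recovery uses n = 200 per class with feature noise
SD 0.1 (alignment 200 epochs, flow 150); the ablation comparison uses
n = 60 per class at noise SD 1.2 across 5 seeds with alignment 60 / flow
250 / fusion ≤ 150 epochs. Recovery of flow class-conditional means is
measured in the aligned subspace as the per-dimension RMS gap between
generated and true class means relative to the within-class latent SD
(the image of the generator's feature noise in the subspace; encoder scale
is arbitrary, so feature-space SDs are not commensurable with latent
distances). The modality-invariance probe uses balanced held-out AD/HC rows
of both modalities — including speech-only MCI rows would let the probe
exploit class identity rather than modality.

Numerical details: all computation in float64; softmax/sigmoid inputs
clipped at ±60 before exponentiation; the center-loss distance uses
sqrt(d² + 1e-12) so its gradient is bounded at the center; epsilon 1e-12 on
power ratios; weight init Kaiming-uniform seeded per network; every source
of randomness (init, masking, dropout, batch order, α, t, x0) derives from
explicit integer seeds and all training loops are bit-reproducible.

## Known limitations

* The affine-Gaussian cohort cannot probe nonlinear modality maps or
  violations of the continuum hypothesis.
* The autodiff engine is minimal by design (dense layers only); it is not a
  general-purpose framework and performs no operator fusion.
* The alignment parameter counts of the reference architecture are not
  exactly reproducible because classifier/discriminator depths admit
  multiple readings; the implemented heads (linear classifier, 128→64→1
  discriminator) are documented choices.
* `flow-only` mode conditions the flow on standardized raw speech features
  and transports to EEG feature space — the closest runnable reading of an
  alignment-free generative baseline.
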