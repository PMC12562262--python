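# Methods

This note documents the modelling and numerical choices behind `pcgvit`:
what is computed, which parameters matter, what the synthetic data does
and does not establish, and where the design was genuinely open.

## Feature extraction

A recording (mono, 2000 Hz; files at other rates are polyphase-resampled)
is framed into 1024-sample windows with hop = window (no overlap).  Per
frame: Hann window → 1024-point FFT → power spectrum → 64 triangular mel
filters spanning 0 Hz–Nyquist on the HTK mel scale
(m = 2595·log₁₀(1+f/700)) → log(energy + 10⁻¹⁰) → orthonormal DCT-II,
all 64 coefficients retained (including the energy-like coefficient 0).
Temporal derivatives use the standard ±2-frame regression
dₜ = Σₙ n(cₜ₊ₙ−cₜ₋ₙ)/(2Σₙ n²) with edge replication; Δ² is the same
operator applied to Δ.  The image is frames × coefficients × {MFCC, Δ, Δ²}.

**Duration handling.** 64 frames of 1024 samples correspond to 65,536
samples (≈32.8 s); corpus recordings run 5–120 s.  Short signals are
zero-padded *in the signal domain* to 64 full windows — padded frames
then carry the constant silent-frame cepstrum DCT(log 10⁻¹⁰·1), and the
Δ-recomputation invariant holds across the whole image.  Long signals are
truncated to the first 64 frames by default; `make_feature_tiles` plus
`predict_tiled` (majority vote over consecutive 64-frame segments, ties
broken by mean probability) are available when discarding everything past
~33 s is unacceptable.  Signal-domain padding also keeps the
partial last window of a short recording (frame-domain padding would
discard those samples).

**Normalization.** Training-set statistics z-score each of the 64×3
coefficient tracks over records and frames (cepstral mean/variance
normalization).  A single scalar per channel was rejected: coefficient 0
is two orders of magnitude larger than the rest, and leaving that range
in place makes the raw images nearly centroid-inseparable (measured
accuracy 0.58 vs 1.00 after CMVN on the synthetic benchmark) and
optimization at the protocol's fixed learning rate unstable.  The
statistics are always fitted on the training fold only and reused for
validation/test.

## Architecture

Both branches consume the identical image.  Branch hyperparameters not
fixed by the architecture description were chosen as: h = 4 heads
(d_s = 16; the parameter count is provably head-count-invariant), MLP
hidden width 4·D = 256, GELU inside the encoder MLP (ViT convention; the
classifier head uses the stated ReLU), no dropout, LayerNorm ε = 10⁻⁶,
Glorot-uniform initialization everywhere with zero biases, biases
included in the Q/K/V/output projections and patch embedding.  Class
tokens are kept in both branches for fidelity to the token-sequence
definition but excluded from the pooled fusion input, whose stated shapes
(256×64 / 64×64) omit the class row; they still receive gradients through
attention.

**Fusion output reading.** Read literally, summing the weighted features
"over the feature dimensions" would produce a scalar, which cannot feed a
64-unit head.  The implemented reading aggregates across the two streams:
f_fused = w_s ⊙ f_s + w_l ⊙ f_l ∈ R⁶⁴, consistent with the head width and
with "a cohesive feature map".  One kernel k is shared by both streams, as
the defining equations reuse the same symbol.  Softmax is taken per
stream over the 64 feature positions — the only axis a 1×64 input offers.
With k = 0 both weight vectors are uniform 1/64 and fusion reduces to
(f_s+f_l)/64, i.e. 2/D times the average baseline; this limit is asserted
in the tests.

**Parameter accounting.** The closed-form count per branch is
P²·C·D + D (embedding) + D + (N+1)·D (class token, positions) +
L·[4D (two LNs) + 4(D²+D) (Q,K,V,U_msa) + D·H+H + H·D+D (MLP)].
Default total: 2 branches (249,920 each in blocks) + embeddings + kernel
(64) + head (8,450) = **544,578 = 0.545 M ≤ 0.86 M**.  The runtime count
must match this formula exactly; the acceptance script enforces it.

## Autodiff and optimization

The package carries its own reverse-mode autodiff over numpy arrays
(broadcast-aware arithmetic, batched matmul, fused linear and layer-norm
primitives, softmax/log-softmax, GELU).  Every backward rule is validated
against central finite differences.  Two numerical policies matter in
practice: python-scalar operands adopt the tensor's dtype so a float32
graph never silently promotes to float64 (the attention maps are the
dominant memory term), and intermediate gradients are freed as soon as
they are consumed during the backward sweep.  Cross-entropy is computed
from logits via log-softmax; inference applies softmax explicitly and
builds no graph.

Training follows the stated protocol exactly: Adam (β₁ = 0.9, β₂ = 0.999,
ε = 10⁻⁷) at lr 0.008 with no scheduling, batch 32, up to 400 epochs,
early stopping after 15 epochs without validation improvement, and
restoration of the best-epoch weights.  "Validation performance" is
accuracy (class-weighted accuracy in 3-class mode) — a maximized
quantity, per the best-weights wording.  NaN/∞ anywhere in the loss path
aborts with a diagnostic rather than continuing silently.  Class
weighting of the loss is available behind a flag and off by default.

## Evaluation protocol

`make_splits` partitions *subjects*: ~10 % (at least one) to a fixed test
set, the rest dealt round-robin into 10 folds after a seeded shuffle.
Disjointness within every fold is an exhaustively tested invariant.
Binary metrics come from TP/TN/FP/FN with "abnormal"/"present" as the
positive class; three-class sensitivity/specificity/F1 are one-vs-rest
macro averages (classes absent from the truth are excluded with a
warning), and weighted accuracy uses Σw_c·diag_c / Σw_c·rowsum_c with the
murmur-challenge weights (present 5, unknown 3, absent 1) — the exact
weights behind the published weighted accuracies are not documented, so
the challenge convention is adopted and configurable.  Reported numbers
are mean ± sd over the fold models evaluated on the common test set.

## Synthetic data

The generator emulates only what the pipeline needs from real corpora:
2 kHz mono signals of 5–120 s (the upper default is 35 s), a subject
structure with several recordings per person, an S1/S2 double-transient
train (damped sinusoids at 30–80 Hz and 80–150 Hz, fixed systole fraction
0.35 of the cardiac cycle, heart rate 55–95 bpm per subject), pink
background noise, and — for murmur-positive classes — band-limited
(150–400 Hz) noise gated to systole at a configurable SNR relative to the
background ("unknown" recordings use SNR −12 dB relative to positives).
It makes no claim to clinical murmur morphology, device/ambient noise
variety, or realistic class priors.  A green end-to-end test therefore
establishes that the implementation can extract, optimize and generalize
a band-limited spectral cue subject-wise — not that it reproduces
published accuracies on real PhysioNet data, which are out of scope.

The standard benchmark used by the learning tests is 40 subjects × 3
recordings at murmur SNR +10 dB, durations 5–15 s (shortened from the
generator default only to bound CPU and disk; the model input is a fixed
64×64×3 image regardless of duration), 2 folds, ≤60 epochs, fixed seeds.

## Known limitations

- The 2016-style loader has no patient identifiers to split by; record
  names serve as subject proxies there, so subject-wise splitting is
  only as good as that proxy.
- Training is CPU-bound numpy; the full 10-fold × 400-epoch protocol on
  real corpora is feasible but slow (hours), and no GPU path exists.
- Fusion operates on pooled vectors; no cross-attention between token
  sequences is provided by design.
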