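# pcgvit

Two-stream vision transformer with attention-based feature fusion for
heart-sound (phonocardiogram, PCG) classification — murmur/abnormality
detection from 2 kHz auscultation recordings, built entirely on
numpy/scipy, including the transformer and its training loop.

## The problem and the model

Screening for cardiovascular disease from heart sounds is hard to do
reliably by ear; automated classifiers work from the recorded
phonocardiogram instead.  This package implements a compact
transformer-based classifier:

1. **Feature image.** Each recording is converted to a fixed 64×64×3
   "image": 64 non-overlapping 1024-sample analysis frames, 64
   mel-cepstral coefficients (MFCCs) per frame, with the MFCC matrix and
   its first (Δ) and second (Δ²) temporal derivatives as three channels.
2. **Two ViT branches.** The same image feeds two vision-transformer
   encoders at different patch granularities: the small-patch branch
   (P=4, 256 patches → a 257×64 token sequence with its class token) sees
   fine time–quefrency detail; the large-patch branch (P=8, 64 patches →
   65×64) sees broader context.  Each branch is a standard pre-LN ViT —
   learnable patch embedding `Z₀ = [x_class; x_p¹E; …; x_pᴺE] + E_pos`,
   then L=5 encoder blocks

       Z'ₗ = MSA(LN(Zₗ₋₁)) + Zₗ₋₁
       Zₗ  = MLP(LN(Z'ₗ))  + Z'ₗ

   with multi-head scaled dot-product attention
   `Attention(Q,K,V) = softmax(QKᵀ/√d_k)V`.
3. **Attention fusion.** Patch tokens of each branch are pooled by global
   average pooling to f_s, f_l ∈ R⁶⁴.  A shared trainable kernel
   k ∈ R⁶⁴ (Glorot-initialized) scores each stream, softmax turns the
   scores into per-feature weights, and the weighted streams are summed:

       s_b = f_b ⊙ k,   w_b = softmax(s_b),   f_fused = w_s ⊙ f_s + w_l ⊙ f_l

   Average / min / max / concatenation fusion are included as ablation
   baselines.
4. **Classifier head.** Three fully connected layers (64-ReLU, 64-ReLU,
   softmax over 2 or 3 classes).

The default model has **544,578 trainable parameters (0.545 M)**, inside
the published 0.86 M budget for this architecture class.

Evaluation follows a subject-wise protocol: 10 % of *subjects* are held
out for testing, 10-fold cross-validation runs over the remaining 90 %,
and no subject ever appears in two subsets of a fold.  Training uses Adam
(lr 0.008, batch 32, ≤400 epochs) with patience-15 early stopping on
validation accuracy and best-epoch weight restoration.  Metrics:
accuracy, sensitivity, specificity, F1, Score = (sensitivity+specificity)/2,
and class-weighted accuracy for the three-class murmur task
(present:5, unknown:3, absent:1).

A synthetic phonocardiogram generator (S1/S2 transient trains plus pink
noise, with band-limited systolic murmur noise at a controllable SNR)
makes the whole pipeline testable without any external data.

## Worked example

```bash
python examples/two_stream_forward.py
```

prints the shape bookkeeping of one forward pass and the parameter count:

```
patches  P=4: (1, 256, 48)   P=8: (1, 64, 192)
encoded tokens  small: (1, 257, 64)   large: (1, 65, 64)
pooled features: (1, 64) (1, 64)
class probabilities: [[0.5024 0.4976]]  (sum = 1.0 )
trainable parameters: 544,578 = 0.545 M (closed form 544,578; budget 0.86 M)
```

i.e. 256 and 64 patches from the same 64×64×3 image, 257×64 / 65×64 token
sequences after the class token is prepended, 64-long pooled features
entering fusion, softmax probabilities out, and an exact match between
the runtime parameter count and the closed-form calculator.

Other examples: `feature_image.py` (signal → MFCC/Δ/Δ² image),
`fusion_modes.py` (the five fusion operators on one feature pair),
`subject_splits.py` (leakage-free split plans), and `train_synthetic.py`
(a scaled-down cross-validated training run on synthetic data, printing
the per-fold metric table).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

builds the default two-stream model from scratch, counts every trainable
scalar at run time, verifies the count against the independent
closed-form calculator, and writes the total in millions of parameters
as JSON.
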