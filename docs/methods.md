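# Methods

## Overview

`mpsfold` predicts nested RNA secondary structure in three stages:

1. **Encoding.** A sequence of length *n* over {A, U, G, C} becomes a
   symmetric *n* × *n* pairing matrix **W**. The base weight reflects
   hydrogen-bond count — P(A,U) = 2, P(G,C) = 3, P(G,U) = *x* with
   *x* ∈ (0, 2), default 0.8 — and each pairable position (i, j) is
   augmented by its potential stem context: neighbouring complementary
   pairs (i−t, j+t) outward and (i+t, j−t) inward contribute with Gaussian
   weight g(t) = exp(−t²/2σ²). Each directional sum truncates at the first
   offset that leaves [1, n], crosses the diagonal (i+t ≥ j−t), or meets a
   non-complementary combination, and at a hard horizon T. A true helix
   therefore appears as an anti-diagonal ridge in **W**, highest in the
   helix interior and decaying toward its ends.
2. **Classification.** Each base is represented by the *d* rows of **W**
   centred on its own row (zero-padded at the sequence ends), resampled to
   *L* columns by corner-aligned bilinear interpolation. A small
   convolutional network maps this *d* × *L* window to a probability
   triple (p_left, p_right, p_point) over the base's dot-bracket label
   "(", ")" or ".".
3. **Decoding.** The *maximum probability sum* dynamic program finds the
   valid nested structure maximising the summed probability of each base's
   assigned label:

       N(i,j) = max{ N(i+1,j) + p_point(R_i),
                     N(i,j−1) + p_point(R_j),
                     N(i+1,j−1) + δ(R_i,R_j),
                     max_{i<k<j} N(i,k) + N(k+1,j) }

   with δ(R_i,R_j) = p_left(R_i) + p_right(R_j) when (R_i,R_j) is an
   allowed pair (A-U, G-C, G-U) enclosing at least `min_loop` bases, and
   p_point(R_i) + p_point(R_j) otherwise. Base cases are N(i,i) =
   p_point(R_i) and N(i,j) = 0 for j < i. This is the Nussinov interval
   recursion with the pair count replaced by label probabilities.

Pair-level evaluation uses sensitivity (recall over reference pairs),
specificity in this literature's sense (precision over predicted pairs),
and their harmonic mean, the F-score.

## Parameters

| knob | default | meaning |
| --- | --- | --- |
| `gu_weight` (x) | 0.8 | G-U wobble weight; 0.8 is the empirically best value for this encoding, and the admissible range (0, 2) keeps wobbles weaker than Watson–Crick A-U |
| `gaussian_sigma` (σ) | 1.0 | stem-context width in base-pair steps; at σ = 1 a neighbour pair contributes e^(−1/2) ≈ 0.61 of its weight |
| `max_offset` (T) | 30 | hard truncation of the stem sums; longer than any realistic helix, so truncation is normally by sequence bounds or mismatch |
| `window_height` (d) | 11 | rows per window, odd so the base's own row is centred; sized to the longest helix of the training family (11 for 5S rRNA-scale data, 19 for mixed-family data) |
| `target_length` (L) | 120 | columns after resampling; the mean sequence length of the training family (120 for 5S rRNA, 128 for mixed families) |
| `conv_blocks` | 3 | convolution + pool blocks; 3 for the single-family geometry (11 × 120), 2 for the general geometry (19 × 128) |
| `kernels_per_conv` | 16 | 3 × 3 kernels per convolution |
| `dense_nodes` | 32 | width of each of the two fully-connected layers |
| `batch_size` / `iterations` | 256 / 400 | mini-batch SGD steps (512 / 2000 in the general setting); "iterations" counts optimiser steps, not epochs |
| `learning_rate` | 0.01 | plain SGD step size |
| `min_loop` | 3 | minimum unpaired bases inside a hairpin; 0 reproduces the bare recursion, 3 is the steric standard |

## Numerical and design choices

- **Stem-sum convention.** The directional stem sums are evaluated on the
  i < j half of the matrix (outward = towards the sequence ends, inward =
  towards the diagonal) and mirrored; the literal formula is
  direction-dependent near the diagonal, and the matrix is symmetric by
  definition. The diagonal is always zero, since no base is complementary
  to itself.
- **Length normalisation** is a corner-aligned linear map (an *n* × *L*
  interpolation matrix applied to each row), so it is deterministic,
  preserves constants exactly, and reduces to the identity when n = L.
  Rows are never resampled; d is fixed by configuration.
- **Pooling** is 3 × 3 max pooling with stride 2 in ceil mode (the input
  is padded with −∞ so the output size is ⌈dim/2⌉). This keeps the stated
  depths compatible with the stated input sizes (11 × 120 through three
  blocks, 19 × 128 through two) and floors the spatial size at 1 × 1, so
  extra depth degrades gracefully instead of failing. Convolutions use
  zero same-padding, stride 1.
- **Initialisation and loss.** Glorot-uniform (Xavier) initialisation,
  softmax + categorical cross-entropy, plain mini-batch SGD. The network
  is implemented directly on numpy arrays with explicit backpropagation;
  the analytic gradients are verified against central differences in the
  test suite. Given (seed, configuration, data order), training is
  bit-for-bit reproducible. Class imbalance (unpaired bases outnumber
  paired ones) is handled by upsampling minority labels with replacement
  to the majority count; originals are always retained.
- **DP base cases** (absent from the bare recursion): N(i,i) = p_point and
  N(i,j) = 0 for j < i make the unpaired-accumulation cases correct on
  two-base intervals.
- **Traceback tie-breaking** follows the written case order (unpair-i,
  unpair-j, close the pair, bifurcation at the smallest split), taking the
  first case that achieves the stored maximum. Candidates are recomputed
  with the same floating-point operations the table fill used, so the
  comparison is exact — no tolerance that could admit a near-tied
  suboptimal case. The bifurcation maximum is vectorised per interval
  length, making the O(n³) fill fast enough for hundreds of ~100-nt
  sequences per second.
- **The δ "not paired" branch** assigns unpaired labels to both interval
  ends; it can reach the same label assignment as the unpair-i/unpair-j
  branches by another route. The optimum is unaffected (verified by
  exhaustive enumeration on all random instances with n ≤ 12), and the
  traceback only ever records a pair when the paired δ applies.
- **Probabilities are used as given** — no renormalisation inside the
  decoder — so any non-negative per-base scores from an external predictor
  can be decoded.
- **Redundancy removal** defaults to exact-duplicate deletion (keep
  first); an optional identity threshold drops sequences whose global
  alignment identity, 1 − editDistance/max(length), reaches the threshold.
  The conservative default never discards data beyond unambiguous
  duplicates.
- **Stem statistics** define a stem as a maximal stack of immediately
  nested pairs; a bulge breaks the stem. The corpus maximum stem length
  and rounded mean sequence length are the recommended (d, L).

## The synthetic data generator

No external structure database is required: the `synth` module draws valid
nested structures by a left-to-right interval walk (pairing propensity
`pair_density`, geometric helix extension `stem_extend` = 0.8, optional
strict `max_stem` cap, minimum loop enforced by construction), fills in
compatible sequences (Watson–Crick pairs with probability 1 −
`gu_fraction`, wobbles otherwise, unpaired positions uniform), and emits
per-base probability tables that place 1 − ε on the true label (ε split
over the others) with seeded Dirichlet jitter at concentration 50; ε = 0
gives exact one-hot tables. Defaults: lengths uniform on [40, 120],
pair_density 0.55, gu_fraction 0.1 — giving helix lengths, pairing
fractions and wobble rates in the range of small structured RNAs.

What the generator does **not** emulate: thermodynamic sequence–structure
consistency (a drawn structure is *a* compatible structure, not the
minimum-free-energy one), family-specific base composition, covariation,
and pseudoknots. End-to-end results on synthetic data therefore
demonstrate that the pipeline is wired correctly and that the decoder
fully exploits informative probabilities — not that the classifier reaches
its published accuracy on curated family data, which requires the real
training corpora.

## Scale of the shipped experiments

The desk-scale end-to-end experiment trains on 500 synthetic sequences
(~40 000 windows at 11 × 120) for the default 400 SGD steps at batch 256,
then predicts, decodes and evaluates 50 held-out sequences. On synthetic
data the learned signal is modest (label accuracy a few points above
chance), but decoded structures recover true pairs well above the
all-unpaired baseline, which is the designed check of the full loop.
Dynamic-programming optimality is verified against exhaustive enumeration
(500 random instances, n ≤ 12), against an independent classic Nussinov
implementation (200 instances), and by exact recovery of 200 noise-free
n = 80 instances.

## Known limitations

- Pseudoknots are out of scope by construction: they are detected and
  filtered, never predicted, and dot-bracket serialisation refuses them.
- The decoder returns one optimal structure; no suboptimal ensembles or
  partition function.
- Windows carry no explicit positional channel, so the classifier must
  infer pairing direction from ridge placement; this limits per-base
  accuracy on data without strong positional regularities.
- Training the classifier to published accuracy requires the original
  curated family datasets, which this package deliberately does not fetch.
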