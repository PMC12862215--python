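# Methods

This note documents the models and procedures `orfcall` implements, the
choices made where the design was genuinely open, and what the bundled
synthetic data can and cannot show.

## The labelling task

Each transcript position belongs to one of three classes: the three
nucleotides of the annotated start codon are TIS, the three of the stop
codon are TTS, everything else (including every position of noncoding
transcripts) is non-site.  Labelling whole codons rather than single
positions reflects how the downstream evaluation defines a correct
call (both 3-nt codon spans exact) and gives the network three times
the positive signal per site.

Sequences are integer-encoded (A,C,G,T→1..4; N and padding→0, sharing
token 0 by design — the loss mask is derived from sequence length,
never from token value).  Transcripts longer than the padded model
length `L_max` are truncated at the 3' end; coding transcripts whose
stop codon falls at or beyond `L_max` are excluded from training with a
logged count, because their labels would be unlearnable.  For real
transcriptomes the documented default for `L_max` is 27,112 nt (the
99.9th length percentile of the human transcriptome); a helper recomputes
that percentile for any input set, and the test suite uses small values.

## Network

Embedding (5×128, padding row frozen at zero) → conv k=3 →
BatchNorm/ReLU (32 ch) → stage 1: four residual blocks, kernel 26,
dilation 1, 32 ch → 1×1 expansion to 64 + BN/ReLU → stage 2: four
blocks, kernel 26, dilation 2 → 1×1 expansion to 128 + BN/ReLU →
stage 3: four blocks, kernel 36, dilation 5 → head 1×1 (128→32) →
ReLU → 1×1 (32→3).  The receptive field is
1 + 2 + 8·25·1 + 8·25·2 + 8·35·5 = 2,003 nt.

Open details and the choices made:

* **Residual block internals.**  Pre-activation layout
  (BN→ReLU→conv→BN→ReLU→conv, identity skip), two convolutions per
  block, constant channel count within a stage.  This is the standard
  residual design consistent with the per-stage kernel/dilation
  parameters.
* **"Same" padding with even kernels.**  Total padding
  `dilation·(kernel−1)`, floor-half left, ceil-half right, so every
  convolution preserves length exactly (including kernels 26 and 36).
* **Padding behaviour.**  Padded positions are zeroed before every
  wide convolution, which makes evaluation-mode logits over the valid
  positions identical whether a transcript runs alone or inside a
  padded batch.  Batch-norm statistics during training are computed
  over all positions of the batch, padding included; evaluation uses
  running statistics (momentum 0.1, eps 1e-5).
* **Residual branch initialisation.**  The last convolution of every
  residual block starts at zero, so each block begins as the identity
  and the branches grow into the computation as training proceeds.
  With twelve wide dilated blocks and batch size 4 this is the
  difference between a network that optimises and one that stalls with
  diffuse, unlocalised site probabilities; the other weights use He
  initialisation.
* **Output bias initialisation.**  The final 1×1 convolution's bias
  starts at the log of nominal class priors (0.02, 0.02, 0.96).  Site
  classes cover only a few percent of positions, and starting from the
  prior spares the optimiser the first epochs of reproducing the
  majority class before it can attend to the sites themselves.  Set
  `head_bias_prior=None` for zero-bias initialisation.
* **Argmax tie-breaking** (raw decoding): NONE wins any tie involving
  it; TIS wins a TIS/TTS tie.  Conservative toward non-calls, matching
  the observation that softmax over imbalanced classes favours the
  majority class.

The network and its training loop are implemented directly in NumPy
(float32) with hand-written backpropagation; dilated convolutions are
computed tap-wise, one GEMM per kernel tap against a zero-padded
input, which keeps the arithmetic inside BLAS.  Gradient correctness
is covered by per-layer and end-to-end finite-difference tests.

## Training

Masked cross-entropy (mean of −log p over non-padding positions), Adam
with initial learning rate 1e-3, batch size 4 by default, at most 50
epochs.  The learning rate halves after 3 consecutive non-improving
validation epochs; training stops after 5; the returned weights are
those of the epoch with the lowest validation loss.  "Improvement"
means lower than the best so far by at least 1e-6 (the tolerance is a
choice; nothing in the regimen pins it), and the scheduler's counter
resets both on improvement and when a reduction fires.

Coding and noncoding transcripts are proportionally mixed in every
batch by a stratified shuffler (cumulative rounding keeps any batch's
coding fraction within 1/batch_size of the global fraction) rather
than by oversampling.  The loss is unweighted — class imbalance is
handled downstream by the integrated scoring system, not by reweighting.
All randomness (initialisation, shuffling) flows from a single config
seed, making runs bit-reproducible on a fixed platform.

## Integrated scoring

Candidates are every (ATG, first in-frame stop) pair — the standard
ORF definition; triplet consistency and stop-termination are the hard
constraints — whose per-codon probabilities pass floors of 0.001.
Per-codon probability is the arithmetic mean of the three
per-nucleotide values (the aggregation is a choice; only
per-nucleotide probabilities are defined upstream).  A cap (default
500 candidates per transcript, strongest by p_TIS+p_TTS kept) bounds
the worst case; oracle tests disable it.

Component conventions:

* **Kozak.**  PWM product over positions −6..+3 around the ATG,
  ×10000 in raw form.  The raw formula is not 0–1; the component
  entering the integrated score is therefore the product divided by
  the maximum attainable product, so the per-position-argmax context
  scores exactly 1.  Flank positions beyond the sequence (and N bases)
  contribute a uniform 0.25.
* **CAI.**  Geometric mean of relative adaptiveness over the ORF's
  sense codons (stop excluded).  The bundled default table derives
  from the standard public human codon-usage frequencies, normalised
  per synonymous family; it is a placeholder for whatever reference
  set a user prefers and is fully replaceable.
* **GC.**  `2·exp(−((gc−0.42)/0.22)²/2)−1` over the candidate ORF
  (stop codon included).  Its range is (−1, 1], not 0–1; the formula
  is kept exactly as specified.  With the default weight of 0 it is
  inert; `gc_rescale=True` maps it to (0, 1] if a nonzero weight is
  used.

Default weights and threshold: 0.30 (TIS), 0.50 (TTS), 0.04 (Kozak),
0.04 (CAI), 0.00 (GC), threshold 0.635 — the grid-search optimum on
validation data.  0.50 (the ROC/Youden-derived cutoff) and 0.52 are
exposed as presets (`THRESHOLD_PRESETS`); different analyses have used
each.  Selection takes the highest-scoring candidate if it clears the
threshold, with deterministic tie-breaks (smaller ATG, then smaller
stop position), so decisions are invariant to candidate order.

`optimize_weights` evaluates the full Cartesian grid of supplied
weight/threshold values, maximising exact-call accuracy (PERFECT for
coding truth, rejection for noncoding), ties to the first point in
lexicographic grid order, and returns the whole accuracy surface for
sensitivity inspection.  `roc_youden` uses the rank/trapezoid AUC and
picks the distinct score maximising sensitivity + specificity − 1.

## Evaluation taxonomy

PERFECT requires both 3-nt codon spans exact.  NEAR_PERFECT means each
boundary within ±1 nt but not both exact (a "single nucleotide
deviation" reading; it takes precedence over TIS_ONLY/TTS_ONLY when
both boundaries are near-misses).  TIS_ONLY / TTS_ONLY: one boundary
exact, the other wrong.  A coding transcript called noncoding falls
under OTHER_ERROR (the taxonomy has no separate bucket for it).
Noncoding truth: CORRECT_NONCODING (no predicted sites), FALSE_ORF
(complete predicted ORF), or the partial-site categories.  Overall
accuracy counts PERFECT and CORRECT_NONCODING only — near-perfect
calls are not credited.  Balanced accuracy is the macro average of the
coding and noncoding accuracies; an explicitly downsampled balanced
set (seeded) is available and agrees in expectation, which a
Monte-Carlo test verifies.

In integrated-scoring mode the "predicted spans" are the selected
candidate's codon spans; in raw mode they are the earliest argmax runs
of each class, and `is_orf` additionally requires a downstream,
in-frame stop.  Both feed the same classifier.

## Perturbation harness

Regions for coding transcripts come from the annotation (5'UTR / CDS /
3'UTR); noncoding transcripts use positional stand-ins — first 5%,
middle 90%, last 5%, with `floor(0.05·len)` flanks (remainder to the
middle).  Indels draw a uniform position inside the region and, for
insertions, uniform bases; each transcript's RNG is seeded from the
condition seed combined with a CRC of the transcript id, so per-
transcript edits are independent yet reproducible.  One perturbation
per transcript per condition.  Truth boundaries strictly downstream of
the edit shift by the net length change; after a frameshifting CDS
indel the shifted "stop" span is usually not a stop codon in frame —
intentionally, because scoring the model against this shifted truth is
precisely what exposes frame sensitivity.  Shuffles permute a region's
bases uniformly (base multiset, hence GC, preserved bit-exactly) and
leave coordinates untouched.  Experiments are evaluated on raw argmax
output, not integrated scoring, so the measured sensitivity reflects
what the network itself learned.

## Synthetic data

The generator emulates the statistical structure the method assumes:

* **Coding:** 5'UTR (background, 8–30 nt) + ATG whose −6..−1 and +3
  context positions are drawn from the Kozak PWM with probability 0.95
  per position (otherwise background) + 13–43 interior sense codons
  drawn from the human codon-usage frequencies (no in-frame stop by
  construction) + a stop codon (TAA/TAG/TGA at roughly human usage) +
  3'UTR (background, 10–40 nt).
* **Noncoding:** i.i.d. background at GC 0.40, resampled (up to 1,000
  tries) until no ATG-initiated, stop-terminated ORF of ≥ 30 codons
  remains; length drawn from the same composite distribution as coding
  transcripts so the classes are not separable by length.  An optional
  flag plants decoy ATGs to harden the task.
* **Genes:** 1–3 isoforms each; isoforms of a coding gene share their
  CDS and differ in UTRs, which is what makes gene-level splitting
  meaningful.

These defaults are a deliberate desk-scale calibration: transcripts are
sORF-length (~90–200 nt, far shorter than real mRNAs) and signal
strength is set so the full-width architecture reaches high held-out
Perfect-ORF rates within a few epochs on a single CPU.  What passing
tests show is that the architecture, loss, scoring system, and
evaluation machinery work end-to-end and that learning behaves as
expected (frameshift sensitivity, scoring improvement over raw argmax).
What they do not show: performance on real transcriptomes — real UTRs
are structured rather than i.i.d., real CDSs are much longer (frame
tracking over thousands of nucleotides), initiation context strength
varies, splicing/uORF/IRES complexity is absent, and class balance
differs.  Numbers obtained on synthetic data are directional, not
estimates of real-data accuracy.

## Problem sizes used by the test suite and acceptance script

The end-to-end runs simulate 1,000 coding + 1,000 noncoding
transcripts (seed-controlled), split 80/20 at the gene level, pad to
`L_max = 400`, and train the full architecture for a small fixed
number of epochs at batch size 4 — sizes chosen so a complete run
stays in the minutes range on one CPU while leaving the architecture
itself unreduced.  Perturbation orderings are measured on 400
freshly simulated coding transcripts (never seen in training).

## Known limitations

* AUG-only initiation; no frameshifting or stop-codon read-through; no
  uORF-specific modelling.
* The NumPy implementation is single-threaded BLAS-bound; it is meant
  for desk-scale experiments, not transcriptome-scale training.
* The bundled CAI table is a generic human reference; species-specific
  analyses should supply their own weights.
* GenBank parsing is deliberately minimal (sequence + first CDS
  feature); genome-coordinate formats (BED/GFF) are out of scope.
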