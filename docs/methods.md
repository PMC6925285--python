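# Methods

## Problem and representation

The package assesses Alzheimer's-disease (AD) likelihood from one-minute
spoken responses to neuropsychological tests (verbal fluency, picture
description, logical memory). Rather than classifying raw audio or full
linguistic transcripts, each response is reduced to a **Feature
Sequence**: an ordered sequence of syllable tokens s₁ … s_T over a closed
token space, with a reserved silence token. The representation keeps
exactly the surface characteristics that differentiate AD speech —
pausing (silence tokens), disfluent repetition (immediate repeats),
vocabulary richness (distinct-token count), and speech quantity (T) —
while discarding content that would make models data-hungry.

The default token space holds 317 Mandarin base syllables plus silence
(318 classes). Base syllables are tone-stripped, which both shrinks the
class count and absorbs accent/tone variation. The exact 317-entry merge
of the original ZhuYin dictionary is not published anywhere we can verify,
so the packaged list is a representative romanized inventory; every
module treats the inventory as an input (one unit per line, UTF-8), so
any language's unit list works. Token ids follow list order with silence
last, so checkpoints are stable across runs.

## Acoustic front-end

80-dimensional log mel-filterbank energies, 25 ms Hann window, 10 ms hop,
FFT size the next power of two ≥ the window, no pre-emphasis, energies
floored at 1e-10 before the log, followed by per-utterance CMVN (zero
mean, unit variance per bin; constant bins map to zero via a variance
floor of 1e-8). CMVN is per-utterance rather than per-corpus so single
utterances can be processed self-contained at inference. Windowing,
FFT sizing and flooring are conventional ASR choices and are
config-exposed; CMVN needs ≥ 2 frames and fails loudly otherwise.

## Feature Sequence Generator (transcriber)

A convolutional-recurrent network maps features to per-frame posteriors
over 318 token classes + 1 CTC blank: three 2-D convolutions (filters
32/32/96, kernels (11,41)/(11,21)/(11,21), batch-norm before a clipped
ReLU capped at 20), five bidirectional GRU layers of 512 cells per
direction (layer-normalized outputs), and a per-frame affine map with
softmax. Trained with CTC loss, Adam at 5e-4, global gradient-norm clip
400, batch 32, Glorot-normal init, utterances > 10 s removed before
batching.

Numerical/design choices the architecture description leaves open:

* **Time strides are 1** in all convolutions, so one output frame covers
  one 10 ms hop. This keeps the silence-threshold arithmetic ("threshold
  divided by 0.01") exact. Deep-Speech-2-style time downsampling would
  contradict that arithmetic; it stays available through config, and the
  decode threshold is always recomputed from the effective frame
  duration. Frequency strides of 2 on the first two convolutions reduce
  compute without affecting the frame rate.
* **Convolution activation** is a clipped ReLU (cap 20), following the
  end-to-end ASR lineage the architecture derives from.
* Layer norm is applied to each recurrent layer's output over the hidden
  dimension; batch norm keeps running statistics (momentum 0.9) for
  inference.
* The CTC recursion runs in the log domain; infeasible targets (more
  labels than frames can carry, counting forced blanks between repeats)
  return +∞ and contribute no gradient, so such samples drop out of the
  batch instead of poisoning it.

**Decoding** is greedy: per-frame argmax (ties to the lowest class id),
then collapse. A maximal run of ≥ N consecutive blank frames emits one
silence token with N = ceil(threshold_s / frame_s) — 300 for the default
3 s threshold at 10 ms; "at least" (≥ N, not > N) matches the worked
arithmetic, and ceil covers non-divisible thresholds with an exactness
guard for float quotients. Shorter blank runs are deleted but still
separate repeated labels; each maximal non-blank run emits one token.
Silence can therefore never collide with the standard CTC repeat merge.

## AD Assessment Engine (classifier)

score = f(s₁ … s_T) ∈ [0,1]: token ids are one-hot encoded (a learned
embedding is available by config; one-hot is the smaller assumption and
is implemented sparsely, as a row gather), fed to a single recurrent
layer — bidirectional GRU with 128 cells per direction by default, tanh
outputs and sigmoid gates — and the final-timestep outputs of both
directions are concatenated into a sigmoid head: score = σ(W y_T + b).
Unidirectional variants default to 256 cells so directionality
comparisons hold the total cell budget fixed. GRU, LSTM and simple cells
are provided; parameter counts order simple < GRU < LSTM at equal size.

Training: cross-entropy **sum** (not mean) over each batch of 16, Adam at
1e-3, Glorot-normal init, early stopping on validation loss with
patience 20, best-validation weights restored; a max-epochs cap
(default 500) guarantees termination. Batches are right-padded; the
forward direction's y_T is read at t = len−1 and the backward direction
runs over each sequence's reversed valid prefix, so padding cannot reach
either final state — scoring a sequence alone or inside any batch agrees
to ≲1e-5 (tested).

## Sequence-quality metrics

Edit distance (unit-cost Levenshtein, DP), token error rate
TER = ED / len(ref) (> 1 possible), and signed length difference
LD = len(hyp) − len(ref), so negative LD means the transcription is
shorter than the reference — the natural reading when a generator
under-transcribes impaired speech. Silence tokens count as ordinary
tokens. ED is verified in tests against a brute-force recursion and the
`edlib` library; it satisfies the metric axioms.

## Evaluation protocol

One trial: seeded shuffle; sequential disjoint test folds of 10 samples
(a smaller trailing fold is allowed when N is not divisible); for each
fold the remaining samples split 85:15 with the validation count
`round-half-up(0.15 × remaining)` (120 samples → 110 remaining → 17
validation / 93 training); a fresh engine is trained per fold and scores
its test fold; fold scores are pooled before computing one AUROC per
trial (plus sensitivity and specificity at threshold 0.5, score ≥ 0.5
predicting AD — the threshold is exposed since the reference procedure
never states one). Trials are averaged; reported spread is the
across-trial standard deviation. AUROC is the midrank Mann–Whitney
statistic, checked in tests against pair counting and scikit-learn.

## Synthetic data

No clinical corpus ships with the package; the generator emulates the
study design (10 + 10 subjects × 6 tests = 120 samples) with a
first-order token model per class: at each position, with probability
`immediate_repeat_prob` copy the previous token; otherwise start a
silence run (geometric length, mean `mean_silence_run`) with a trigger
probability solved so the stationary silence fraction equals
`silence_rate`; otherwise draw uniformly from the class's active
vocabulary. Length is a rounded normal around `mean_length`
(sd = 0.15 × mean, floor 2). Defaults: CH length 150, silence 0.05,
repeat 0.05, vocabulary 40, run 1.2; AD length 60, silence 0.30, repeat
0.25, vocabulary 15, run 2.0. Effect sizes are intentionally large so
desk-scale recovery experiments are stable; true clinical effect sizes
are not derivable from published per-class statistics, and passing
recovery tests therefore demonstrates pipeline correctness, not clinical
performance. Real speech differs in ways the model ignores: token
dependencies beyond first order, test-type-specific content, speaker
idiosyncrasy, and transcription noise correlated with disease severity.

The corruption model (independent per-token substitution/deletion plus
geometric insertions) emulates automatic-transcription errors for
robustness experiments; with only substitutions at rate p the expected
TER is p. Toy audio renders tokens as 0.2 s sinusoids (distinct
frequencies, silence as near-zero noise) with exact frame alignments, so
the CTC transcriber can be trained and audited end to end without any
speech corpus.

## Problem sizes and seeds

All experiments are deterministic given their seeds (numpy `Generator`
throughout; fold plans, cohort draws and weight inits all derive from
explicit seeds). The shipped recovery experiment uses the 120-sample
default cohort, a 16-cell-per-direction bidirectional GRU, 3 trials of
the 12-fold protocol, and the toy transcriber uses a one-conv /
one-biGRU-layer config (12 cells/direction, 20 mel bins, 8 kHz) trained
for 500 iterations at 3e-3 — the tiny network tolerates a larger step
size than the full recipe and needs it to leave the early all-blank CTC
regime quickly. Full-scale configs (5×512 biGRU, 50 000 iterations)
are constructible from the same classes but are not exercised by the
test suite.

## Known limitations

* The numpy implementation is CPU-only and unsuited to the full 422-hour
  ASR training regime the full-scale transcriber would need.
* Greedy decoding only; no beam search or language model.
* The engine scores whole sequences; no attention, no per-test-type
  models, and fine-tuning on automatically transcribed sequences is
  supported only as generic continued training.
* The packaged syllable list is representative, not the unpublished
  clinical one; results on it are exchangeable with any other inventory
  of the same size.
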