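# Methods

This note documents the models and procedures `chunkclin` implements, the
assumptions behind the synthetic data it is tested on, the numerical and
design choices that were genuinely open, and the limits of what the test
suite demonstrates.

## The classification problem

Six binary labels per clinical note — history of cancer (`cancer`),
unexplained weight loss (`weight`), fever (`fever`), recent infection
(`infection`), loss of bowel/bladder control (`bowel`), abnormal
reflexes / loss of leg muscle power (`abreflex`) — in that fixed order
throughout the package. A note with all six at 0 is the *null class*.
The operating regime is a corpus of a few thousand notes in which the null
class dominates (~87%) and the rarest labels appear in well under 1% of
notes, so every design decision below is about imbalance or input length.

## Chunked-encoder classifier

**Chunking.** A note is tokenized and split into consecutive windows of
`max_tokens_per_chunk − 2` content tokens (default 510); each window gets
its own start/end markers so every chunk is a well-formed encoder input.
Overlap defaults to 0 — chunks partition the sequence, and with overlap 0
stripping the markers and concatenating the chunks reproduces the token
sequence exactly (unit-tested). Notes beyond `max_chunks` (default 3,
matching a 1400-token maximum at 512-token chunks) are truncated with a
warning.

**Chunk embeddings.** For each chunk, token states are averaged over the
encoder's last five layers and then over non-padding token positions
(the two means commute for plain averages; also unit-tested). Shallower
encoders use all their layers with a warning.

**Aggregation head.** The chunk-embedding matrix (n_chunks × width) is
convolved along the *chunk axis* — kernel widths {2, 3}, 64 filters per
width, ReLU, max-over-time pooling, dropout 0.1, linear layer, sigmoid.
This is the word-sequence text-CNN design transplanted to chunk sequences;
widths are small because chunk sequences rarely exceed three items, and
sequences shorter than the largest kernel are zero-padded. A flat
concatenation of chunk embeddings into one vector was rejected because it
fixes the input length. `multitask` mode uses one backbone and a 6-output
head; `binary` mode trains six fully independent single-output models
(≈6× the parameters — the ratio is slightly below 6 because the multitask
head is 5·(features+1) weights larger than one binary head).

**Backbone.** Any encoder exposing per-layer hidden states fits the
interface. The bundled backbone is a small BERT-style transformer
(2 layers, width 32, 2 heads, GELU feed-forward of 64, learned positions)
implemented in numpy on the package's reverse-mode autodiff engine; it is
the default for every experiment so the whole stack is CPU-deterministic.
The bundled tokenizer is word-level (lowercased whitespace) with
[PAD]/[UNK]/[CLS]/[SEP]/[MASK] specials: it keeps the chunk-reconstruction
invariant exact and its vocabulary aligned with the synthetic generator.

**Training.** Per-label binary cross-entropy on sigmoid outputs
(the standard multi-label choice), Adam, seeded shuffling, minibatch 8.
`TrainConfig` defaults to 10 epochs at learning rate 5e-5 — the published
fine-tuning range for large pretrained encoders. The tiny from-scratch
backbone needs a larger step; experiments here use 1e-3 to 1.5e-3 for
6–12 epochs, passed explicitly. With a fixed seed the loss trace is
bit-reproducible; with learning rate 0 parameters are provably unchanged.

**Domain adaptation.** Continued pretraining of the backbone on unlabeled
notes, masked (MLM: 15% of content tokens, 80/10/10 mask/random/keep,
masked-token cross-entropy) or causal (CLM: next-token cross-entropy under
a causal attention mask), 3 epochs by default. The language-model head is
trained jointly and discarded; the adapted weights become the backbone
*initialization* for subsequent fine-tuning, surviving the fresh-parameter
reset that `fit` performs. Adaptation uses a gentler learning rate
(5e-4) than fine-tuning: aggressive adaptation drifts the weights far from
a well-conditioned init and measurably hurts downstream AUROC.

## Annotation enrichment by semantic similarity

Rare labels are enriched by ranking an unlabeled pool against per-label
queries: the concatenation (corpus order) of every rationale snippet
annotators highlighted for that label, or a definition/custom fallback
when no rationale exists yet. Ranking is cosine similarity on
unit-normalized sentence embeddings; the top K (convention 10–50,
default 25) are kept, then filtered by label-specific evidence phrases
(read as a *keep-if-matching* include list — the canonical filter phrases
are positive indicators — with an optional exclude list). Ties are broken
by note id so rankings are reproducible; already-labeled notes are excluded
from the pool; per-label batches may overlap and a deduplicated union is
reported.

The default encoder is deliberately lexical: tf-idf (unigram, L2) computed
over the batch passed to a single `embed` call, so the query and pool share
one vocabulary and identical batches give identical vectors. Trained
sentence encoders (denoising-autoencoder or contrastive objectives) plug in
behind the same `embed(texts)` interface; their training is out of scope.

## Evaluation harness

**Iterative stratification.** Greedy multi-label fold assignment: process
the label with the fewest remaining examples first; assign each of its
examples to the fold with the greatest remaining demand for that label;
break ties by remaining fold capacity, then seeded-randomly. Fold
capacities are fixed at floor/ceil(n/k), so fold sizes differ by at most
one; null-class notes fill remaining capacity last. On a single-label
corpus with the study's counts this forces the published split exactly
(folds of 1374/1375; 53 cancer notes split 26/27).

**Downsampling.** Null-class *training* notes are sampled without
replacement down to the any-positive count; positives are kept identically;
the test split is never touched. 347 positives + 2402 nulls → 694 training
notes.

**AUROC.** Rank-based (Mann–Whitney with midrank ties), via
scikit-learn; undefined (not 0.5-imputed) when a test split has a single
class for a label, and undefined labels are excluded from that run's macro
average — with ~4 positives of a rare label per fold, imputation would
systematically drag the macro toward 0.5. Macro averages labels within a
run, then runs; SDs are across the 4 runs (2 folds × 2 repeats, ddof=1).

**Baseline.** Unigram tf-idf (sublinear tf off, L2) + one L2-regularized
logistic classifier per label at default strength; single-class labels get
constant prior scores and are flagged.

## Synthetic data generator

The generator emulates the documented statistics of the study corpus, not
its language. Defaults: 2749 notes; per-label marginals equal to the final
annotation counts over 2749 (cancer 53, weight 32, fever 17, infection 9,
bowel 9, abreflex 236); null fraction 2402/2749; lengths from a lognormal
(μ=4.833, σ=1.0) clipped to [7, 1400] tokens, putting ~8% of notes above
512 tokens; 22 sites and ~1.41 notes per patient (notes-per-patient
1 + Poisson, patients assigned uniformly to sites).

Labels are drawn independently *conditioned on the note being positive*;
the conditional probabilities are calibrated by a short fixed-point
iteration so the unconditional marginals match the targets despite
rejection of all-zero draws (co-occurrence is not modeled — the study
reports none). Every positive label is witnessed by an evidence snippet
injected verbatim at recorded character offsets; placement is uniform, or
forced past a configurable chunk boundary for a chosen fraction of positive
notes (the regime where truncating classifiers fail). Confuser phrases
drawn from the study's exclusion criteria (HIV, urinary symptoms other than
incontinence, shingles, enuresis, degenerative disease, pasted imaging
results, resolved back pain, well-child visits) are injected into notes of
any class and never flip a label. Same spec + same seed ⇒ byte-identical
corpus; "tokens" here are whitespace words (the length statistics describe
note size, not any specific tokenizer).

What passing tests on this data do **not** show: robustness to negation,
abbreviation, misspelling, template boilerplate, or evidence phrased
differently from the snippet banks — i.e., results here bound the
machinery, not clinical performance.

## Problem sizes used in the checks

All experiment routines (`chunkclin.experiments`) run at desk scale,
chosen so the full suite completes in minutes on one CPU:

* end-to-end pipeline: 300-note corpus (70% null), 400-note pool, 2-fold
  CV, tiny backbone, 12 epochs;
* long-note advantage: 200 notes, chunk capacity scaled to 30 content
  tokens with evidence forced past the first chunk in 80% of positives,
  chunked vs truncated over 5 seeds;
* downsampling comparison: 400 notes, 88% null, weak combination-only
  signal, 5 seeds;
* MLM adaptation: 240 notes + 250-note pool, 3 adaptation epochs,
  4 fine-tuning epochs, 5 seeds;
* sampling enrichment: 120 labeled notes, 400-note pool, K=25, 10 seeds.

## Known limitations and one negative result

* The downsampling comparison is directionally *negative* at this scale:
  across every condition tried (baseline and neural model, strong/weak
  signal, null fractions 0.85–0.95, scratch and adapted initializations)
  removing null training notes cost 0.04–0.18 macro-AUROC. A tiny model
  trained from scratch on a few hundred notes is data-limited, so the
  information lost with the discarded nulls outweighs the benefit of class
  balance; the published gain arises with a heavily pretrained encoder on a
  larger real corpus where representations are not learned from the labeled
  data. The corresponding acceptance test asserts the non-inferiority
  property as specified and is expected to fail; the acceptance script
  reports the measured (negative) delta.
* The numpy backbone is intentionally small; nothing here measures how the
  architecture scales to pretrained clinical encoders.
* The word-level tokenizer cannot represent subword regularities; plug in a
  subword tokenizer alongside a matching backbone for real text.
* The lexical sampler's embeddings are batch-relative (idf computed over
  query + pool); rankings are comparable within a call, not across pools.
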